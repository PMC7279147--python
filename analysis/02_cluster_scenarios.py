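"""Contact clustering of the DNA chains in the scripted aggregates.

Two scripted scenarios mimic the qualitative behaviours seen in the
simulated nanotube/DNA systems: an unprotonated-coil system where five of
six chains collectively aggregate (one detaches, giving 2 clusters), and
a protonated system where chains move individually and the count
oscillates between 4 and 5.  Clustering uses the 3.5 Å single-linkage
contact criterion with nanotube, ligand, water and ion atoms excluded.
Per-frame counts and window summaries go to results/cluster_summary.tsv.
"""

from pathlib import Path

from imotif_md.builders import make_scenario, preset_b1, preset_b3
from imotif_md.contacts import cluster_timeseries

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = ["scenario\tframes\tmin\tmax\tmode\tterminal"]
    for name, preset in (("collective-aggregate", preset_b1),
                         ("individual-chains", preset_b3)):
        traj, truth = make_scenario(preset())
        _, summary = cluster_timeseries(traj)
        rows.append(f"{name}\t{len(traj)}\t{summary.min_count}\t"
                    f"{summary.max_count}\t{summary.modal_count}\t"
                    f"{summary.terminal_count}")
        planted = sorted(set(truth.cluster_counts))
        print(f"{name}: planted counts {planted}, measured range "
              f"({summary.min_count}, {summary.max_count}), "
              f"mode {summary.modal_count}")
        assert summary.counts.tolist() == truth.cluster_counts
    (OUT / "cluster_summary.tsv").write_text("\n".join(rows) + "\n")
    print(f"\nwrote {OUT / 'cluster_summary.tsv'}")
    print("Finding: the analysis recovers the scripted partitions "
          "exactly — 2 clusters for the collective aggregate, a 4-5 "
          "oscillation for individually moving chains.")


if __name__ == "__main__":
    main()
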