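"""Tree extraction and topology: individual and group MSTs, metrics,
occurrence tables, and overlap with the control-group reference tree.

Reads the per-subject tPLV matrices from results/connectivity/, extracts the
maximum-connectivity spanning tree of each (Kruskal), computes nodal and
global metrics, builds each group's tree from its average connectivity
matrix, and measures every subject's edge overlap with the reference tree
(from the control-group average matrix).
"""

from pathlib import Path

import pandas as pd

from plvtree.connectivity import gplv
from plvtree.graph_metrics import global_metrics, occurrence, overlap
from plvtree.mst import group_tree, kruskal_max_tree
from plvtree.workflow_io import load_cohort, read_matrix, write_tree

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_cohort(ROOT / "cohort")
    conndir = ROOT / "connectivity"
    outdir = ROOT / "topology"
    outdir.mkdir(parents=True, exist_ok=True)

    matrices, trees, groups = {}, {}, {}
    for _, record in cohort:
        conn = read_matrix(conndir / f"{record.subject_id}_tplv.tsv")
        matrices[record.subject_id] = conn
        trees[record.subject_id] = kruskal_max_tree(conn)
        groups.setdefault(record.group, []).append(record.subject_id)

    reference = group_tree([matrices[s] for s in groups["control"]])
    write_tree(outdir / "reference_mst.tsv", reference)

    rows = []
    for _, record in cohort:
        sid = record.subject_id
        gm = global_metrics(trees[sid], gplv=gplv(matrices[sid]))
        row = {"subject_id": sid, "group": record.group,
               "disease_duration": record.disease_duration,
               "alsfrs_r": record.alsfrs_r,
               "clinical_score": record.clinical_score}
        row.update(gm.as_dict())
        row["overlap_percent"] = overlap(trees[sid], reference).overlap_percent
        rows.append(row)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                   float_format="%.12g")

    for name, ids in groups.items():
        gtree = group_tree([matrices[s] for s in ids])
        write_tree(outdir / f"group_mst_{name}.tsv", gtree)
        occ = occurrence([trees[s] for s in ids])
        occ.hub_frame().to_csv(outdir / f"hub_occurrence_{name}.tsv", sep="\t",
                               index=False, float_format="%.12g")
        occ.edge_frame().to_csv(outdir / f"edge_occurrence_{name}.tsv", sep="\t",
                                index=False, float_format="%.12g")
        ggm = global_metrics(gtree)
        print(f"group MST [{name}]: k_max={ggm.k_max} "
              f"L_f={ggm.leaf_fraction:.2f} D={ggm.diameter:.2f} "
              f"T_H={ggm.tree_hierarchy:.2f}")

    summary = metrics.groupby("group")[
        ["k_max", "leaf_fraction", "diameter", "kappa", "eccentricity",
         "overlap_percent"]
    ].mean().round(2)
    print("\nindividual-tree group means:")
    print(summary)


if __name__ == "__main__":
    main()
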