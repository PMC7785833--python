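"""Phase-locking connectivity: epochs -> tPLV adjacency matrix per subject.

For every subject in results/cohort/: Hilbert instantaneous phase over the
full 20-s epochs, trial-averaged PLV per channel pair and sample, z-scoring
against the [-4, -1) s baseline, and averaging over the [0, 12) s
post-stimulus window (M = 94 samples at 7.81 Hz).  Writes one labelled
14 x 14 tPLV matrix per subject and a per-subject global PLV table.
"""

from pathlib import Path

import pandas as pd

from plvtree.connectivity import gplv
from plvtree.workflow_io import load_cohort, subject_connectivity, write_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_cohort(ROOT / "cohort")
    outdir = ROOT / "connectivity"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for epochs, record in cohort:
        conn = subject_connectivity(epochs)
        write_matrix(outdir / f"{record.subject_id}_tplv.tsv", conn)
        rows.append({"subject_id": record.subject_id, "group": record.group,
                     "gplv": gplv(conn), "m_samples": conn.m_samples})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "gplv.tsv", sep="\t", index=False, float_format="%.12g")
    print(f"wrote {len(rows)} tPLV matrices (M = {rows[0]['m_samples']} samples)")
    print(table.groupby("group")["gplv"].agg(["mean", "std"]).round(3))


if __name__ == "__main__":
    main()
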