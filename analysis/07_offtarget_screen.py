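#!/usr/bin/env python
"""Sequence screens used in reagent design: mismatch-tolerant search for
regions complementary to the two anti-env shRNA guides across a synthetic
transcript set, and least-variable-window selection on an alignment for
primer placement.

Writes offtarget_hits.tsv and conserved_window.tsv under results/.
"""

from pathlib import Path

import pandas as pd

import retrostress as rs

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 1

GUIDES = {
    "shRNA-Env1": "CCTGAACATCCAGAATTAT",
    "shRNA-Env1070": "CCTCGAGGTCAATTCTACCACAATT",
}


def main() -> None:
    BASE.mkdir(exist_ok=True)
    rows = []
    for name, guide in GUIDES.items():
        fx = rs.generate_sequences(guide, n_transcripts=30, transcript_len=1500,
                                   n_exact_sites=3, n_one_mismatch_sites=2, seed=SEED)
        fasta = BASE / f"transcripts_{name}.fasta"
        rs.write_fasta(fx["transcripts"], fasta)
        transcripts = rs.read_fasta(fasta)
        for mm in (0, 1):
            hits = rs.find_complementary_sites(guide, transcripts, mm)
            print(f"{name} ({len(guide)} nt): {len(hits)} complementary regions "
                  f"with <= {mm} mismatch(es) across 30 transcripts")
            if mm == 1:
                for h in hits:
                    rows.append({"guide": name, "seq_id": h.seq_id, "start": h.start,
                                 "end": h.end, "mismatches": h.mismatches})
        planted = fx["manifest"]["sites"]
        assert len(rows) >= len(planted)
    pd.DataFrame(rows).to_csv(BASE / "offtarget_hits.tsv", sep="\t", index=False)

    fx = rs.generate_sequences(GUIDES["shRNA-Env1"], aln_n_seqs=8, aln_len=200,
                               conserved_start=75, conserved_len=24, seed=SEED)
    win = rs.least_variable_window(fx["alignment"], 24)
    pd.DataFrame(
        [{"start": win.start, "end": win.end, "mean_variability": round(win.score, 4)}]
    ).to_csv(BASE / "conserved_window.tsv", sep="\t", index=False)
    lo, hi = fx["manifest"]["conserved_window"]
    print(f"least variable 24-nt window: [{win.start}, {win.end}) "
          f"(planted conserved block [{lo}, {hi})) -> primer target")


if __name__ == "__main__":
    main()
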