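#!/usr/bin/env python
"""Sliding-window genotype correction of the RIL calls (15-SNP window,
majority threshold 11) and the per-individual correction report."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from binqtl import genocorrect, io
from common import outdir, scratchdir

sim = scratchdir("sim")
out = outdir("correct")
raw = scratchdir("correct")

calls = io.read_vcf(sim / "ril_calls.vcf")
corrected = genocorrect.slide_correct(calls)
report = genocorrect.correction_report(calls, corrected)

io.write_vcf(corrected, raw / "ril_corrected.vcf")
report.to_csv(out / "corrections.tsv", sep="\t", index=False)

total = int(report["count"].sum())
per_ind = report.groupby("individual")["count"].sum()
by_type = report.groupby("transition")["count"].sum().sort_values(ascending=False)
print(f"corrected {total} calls "
      f"({total / calls.calls.size:.2%} of the matrix); "
      f"median {per_ind.median():.0f} per line")
print("top transitions:")
print(by_type.head(6).to_string())
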