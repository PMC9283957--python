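#!/usr/bin/env python
"""Candidate-gene triage on the 24-gene interval fixture: expression,
differential-expression, variant-effect and synteny evidence combined by the
ordered retain/exclude rules."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from binqtl import triage
from binqtl.simpop import CANDIDATE_INTERVAL, make_triage_fixture
from common import outdir

out = outdir("triage")
fx = make_triage_fixture()
for name, df in fx._asdict().items():
    df.to_csv(out / f"input_{name}.tsv", sep="\t", index=False)

chrom, lo, hi = CANDIDATE_INTERVAL
genes = triage.genes_in_interval(fx.genes, chrom, lo, hi)
records = triage.annotate_genes(genes, fx.expression, fx.de_stats, fx.variants, fx.synteny)
verdicts = triage.triage_genes(records, syntenic_region_has_qtl=False)
table = triage.verdict_table(verdicts)
table.to_csv(out / "verdicts.tsv", sep="\t", index=False)

print(f"interval {chrom}:{lo:,}-{hi:,} ({(hi - lo) / 1000:.0f} kb): "
      f"{len(genes)} genes")
print(table.groupby(["verdict", "reason"]).size().to_string())
retained = table.loc[table["verdict"] == "retained", "gene_id"].tolist()
print("candidate genes:", ", ".join(retained))
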