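#!/usr/bin/env python
"""Simulate the study populations: an F2:11 RIL population with planted QTLs
and multi-environment phenotypes, and a structured diversity panel.

Writes VCF + phenotype + truth files under results/sim/ and prints the
realized design quantities.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from binqtl import io, simpop
from common import SIM, outdir, ril_map, scratchdir

out = outdir("sim")
raw = scratchdir("sim")
gmap = ril_map()

calls, truth = simpop.simulate_ril_population(gmap, SIM)
pheno = simpop.simulate_phenotypes(truth, calls, SIM)
panel, labels = simpop.simulate_structured_panel(SIM)
panel_pheno = simpop.simulate_polygenic_phenotype(panel, h2=0.5, seed=SIM.seed)

io.write_vcf(calls, raw / "ril_calls.vcf")
io.write_phenotypes(pheno, out / "ril_phenotypes.tsv")
io.write_truth_json(truth, raw / "ril_truth.json")
io.write_vcf(panel, raw / "panel_calls.vcf")
pd.DataFrame({"accession": panel.samples, "subpop": labels}).to_csv(
    out / "panel_subpops.tsv", sep="\t", index=False
)
panel_pheno.rename_axis("accession").reset_index().to_csv(
    out / "panel_phenotype.tsv", sep="\t", index=False
)

het = float((calls.calls == 1).mean())
n_junctions = np.mean(
    [sum(len(truth.breakpoints(i, c.id)) for c in gmap.chromosomes)
     for i in range(SIM.n_ril)]
)
print(f"RIL population: {SIM.n_ril} lines x {calls.n_markers} SNPs "
      f"({len(gmap.chromosomes)} chromosomes)")
print(f"residual heterozygosity {het:.4f} (expected ~ 0.5^{SIM.n_self_generations} "
      f"= {0.5 ** SIM.n_self_generations:.4f} before error)")
print(f"mean junctions per line: {n_junctions:.2f}")
print(f"realized per-environment h2: "
      + ", ".join(f"{k}={v:.2f}" for k, v in truth.realized_h2_per_env.items()))
print(f"panel: {panel.n_individuals} accessions x {panel.n_markers} SNPs, "
      f"{len(np.unique(labels))} subpopulations")
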