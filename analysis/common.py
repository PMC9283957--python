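"""Shared study configuration for the numbered analysis drivers.

One simulated 'study': a 158-line F2:11 RIL population genotyped at 100
SNPs/cM on two 50-cM chromosomes with one major seed-oil QTL, phenotyped in
nine environments at entry-mean h2 ~ 0.785, plus a 204-accession structured
panel for association.
"""

from pathlib import Path

from binqtl import qtlscan, simpop

SEED = 1
_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"
SCRATCH = _ROOT / "scratch"  # bulky intermediates (full call matrices etc.)

RIL_MAP = dict(n_chrom=2, bp_length=20_000_000, cm_length=50.0, snps_per_chrom=5000)

QTL = [simpop.QtlSpec("A01", 10_000_000, 0.9), simpop.QtlSpec("A02", 4_000_000, 0.4)]

SIM = simpop.SimConfig(
    seed=SEED,
    n_ril=158,
    qtl_spec=QTL,
    n_environments=9,
    n_replicates=3,
    target_h2=0.7854,
    panel=simpop.PanelConfig(
        n_accessions=204,
        k_subpops=4,
        fst=0.15,
        chromosomes=(("A01", 10_000_000, 1500), ("C01", 10_000_000, 1000)),
        ld_decay_bp=100_000,
    ),
)

SCAN = qtlscan.ScanSettings(n_permutations=500)


def ril_map():
    return simpop.uniform_map(**RIL_MAP)


def outdir(name: str) -> Path:
    p = RESULTS / name
    p.mkdir(parents=True, exist_ok=True)
    return p


def scratchdir(name: str) -> Path:
    p = SCRATCH / name
    p.mkdir(parents=True, exist_ok=True)
    return p
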