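"""Rule-based candidate-gene triage inside a QTL interval.

For an allopolyploid like B. napus, a QTL interval on one subgenome usually
has a syntenic block on the other; a gene whose syntenic partner shows the
same expression behaviour and which carries no coding-sequence variant
between the mapping parents is unlikely to explain a QTL absent from the
partner block.  The triage combines seed expression, differential
expression, variant-effect annotation and synteny into ordered
retain/exclude rules:

R1  genes expressed in neither parent at any timepoint are excluded;
R2  if the syntenic region carries no QTL, genes with no syntenic partner
    are retained (they cannot be explained away by a partner);
R3  genes whose every syntenic partner has a coincident expression profile
    (log-scale Pearson correlation >= the threshold and identical DEG
    status) and which carry no coding-sequence variant are excluded;
R4  remaining differentially expressed genes are retained;
R5  everything else is retained by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CDS_EFFECTS = frozenset({"missense", "synonymous"})
EFFECT_CLASSES = frozenset(
    {"missense", "synonymous", "upstream", "downstream", "UTR", "intron"}
)


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    expression: np.ndarray  # per parent x timepoint levels (FPKM scale)
    expressed: bool
    is_deg: bool
    variant_effects: list[str] = field(default_factory=list)
    partners: list[str] = field(default_factory=list)
    partner_expression: dict[str, np.ndarray] = field(default_factory=dict)
    partner_deg: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class TriageVerdict:
    gene_id: str
    verdict: str  # "retained" | "excluded"
    reason: str


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------


def deg_filter(stats: pd.DataFrame, l2fc_min: float = 1.0, padj_max: float = 0.05) -> pd.Series:
    """DEG flags from a differential-expression statistics table (columns
    ``gene_id``, ``log2fc``, ``padj``; one row per gene per contrast): a gene
    is flagged iff |log2FC| > 1 and padj < 0.05 in any contrast.  Strict
    inequalities; missing padj never flags (with a warning)."""
    df = stats.copy()
    if df["padj"].isna().any():
        warnings.warn("rows with missing padj are never flagged as DEG", stacklevel=2)
    hit = (df["log2fc"].abs() > l2fc_min) & (df["padj"] < padj_max)
    return hit.groupby(df["gene_id"]).any()


def genes_in_interval(genes: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Genes whose span overlaps [start, end] on ``chrom`` (any overlap,
    including genes straddling the interval edges)."""
    if end < start:
        return genes.iloc[0:0]
    hit = (genes["chrom"] == chrom) & (genes["start"] <= end) & (genes["end"] >= start)
    return genes[hit].reset_index(drop=True)


def annotate_genes(
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    de_stats: pd.DataFrame,
    variants: pd.DataFrame,
    synteny: pd.DataFrame,
    expressed_cutoff: float = 0.5,
) -> list[GeneRecord]:
    """Assemble :class:`GeneRecord` objects from the five input tables.

    ``expression`` has one row per gene (column ``gene_id``) and one column
    per parent-timepoint sample; a gene counts as expressed when any sample
    exceeds ``expressed_cutoff``.  Syntenic partners' expression profiles and
    DEG flags are attached from the same tables.
    """
    samples = [c for c in expression.columns if c != "gene_id"]
    expr = expression.set_index("gene_id")[samples]
    deg = deg_filter(de_stats)
    var_by_gene = variants.groupby("gene_id")["effect"].apply(list)
    bad = set().union(*var_by_gene) - EFFECT_CLASSES if len(var_by_gene) else set()
    if bad:
        raise ValueError(f"unknown variant effect classes: {sorted(bad)}")
    partners = synteny.groupby("gene_id")["partner_id"].apply(list)

    records = []
    for row in genes.itertuples(index=False):
        gid = row.gene_id
        if gid not in expr.index:
            raise ValueError(f"gene {gid} missing from the expression table")
        prof = expr.loc[gid].to_numpy(dtype=float)
        plist = partners.get(gid, [])
        p_expr, p_deg = {}, {}
        for pid in plist:
            if pid not in expr.index:
                raise ValueError(f"syntenic partner {pid} missing from expression table")
            p_expr[pid] = expr.loc[pid].to_numpy(dtype=float)
            p_deg[pid] = bool(deg.get(pid, False))
        records.append(
            GeneRecord(
                gene_id=gid,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                expression=prof,
                expressed=bool((prof > expressed_cutoff).any()),
                is_deg=bool(deg.get(gid, False)),
                variant_effects=list(var_by_gene.get(gid, [])),
                partners=plist,
                partner_expression=p_expr,
                partner_deg=p_deg,
            )
        )
    return records


def _coincident(rec: GeneRecord, pid: str, threshold: float) -> bool:
    a = np.log2(rec.expression + 1.0)
    b = np.log2(rec.partner_expression[pid] + 1.0)
    if a.std() == 0 or b.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    return corr >= threshold and rec.partner_deg[pid] == rec.is_deg


# --------------------------------------------------------------------------
# the triage itself
# --------------------------------------------------------------------------


def triage_genes(
    records: list[GeneRecord],
    syntenic_region_has_qtl: bool = False,
    coincidence_threshold: float = 0.8,
) -> list[TriageVerdict]:
    """Apply the ordered rules R1-R5 to every interval gene.

    Every gene receives exactly one verdict; the reason code names the first
    rule that fired.
    """
    verdicts = []
    for rec in records:
        if rec.expression is None:
            raise ValueError(f"gene {rec.gene_id} is not annotated")
        if not rec.expressed:
            verdicts.append(TriageVerdict(rec.gene_id, "excluded", "not_expressed"))
            continue
        if not syntenic_region_has_qtl and not rec.partners:
            verdicts.append(TriageVerdict(rec.gene_id, "retained", "unique_gene_retained"))
            continue
        has_cds_variant = any(e in CDS_EFFECTS for e in rec.variant_effects)
        if (
            rec.partners
            and not has_cds_variant
            and all(_coincident(rec, pid, coincidence_threshold) for pid in rec.partners)
        ):
            verdicts.append(
                TriageVerdict(rec.gene_id, "excluded", "synteny_coincident_no_cds_variant")
            )
            continue
        if rec.is_deg:
            verdicts.append(TriageVerdict(rec.gene_id, "retained", "deg_retained"))
            continue
        verdicts.append(TriageVerdict(rec.gene_id, "retained", "default_retained"))
    return verdicts


def verdict_table(verdicts: list[TriageVerdict]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in verdicts])
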