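"""Gene-set-level analyses around the benchmark comparison.

Covers: filtering zonation (periportal/pericentral) modules down to genes
actually enriched in PHH/liver over the other cell-model sources; selecting
differentially expressed genes from an externally computed DE table;
log2-odds enrichment scores of pathways in up/down gene lists; and the
concordance between transcript and protein log-ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import FormatError, ValidationError
from .io import GeneSet, SampleMetadata, PHH_SOURCE
from .normalize import NormalizedMatrix


@dataclass
class ZonationModule:
    """A zonation gene module restricted to PHH/liver-enriched members."""

    name: str
    input_genes: frozenset[str]
    retained_genes: frozenset[str]
    fold_threshold: float
    enrichment: pd.Series  # per-gene mean(PHH) - mean(pooled others), log2 scale

    def as_gene_set(self) -> GeneSet:
        return GeneSet(name=self.name, description="PHH-enriched zonation module",
                       gene_ids=self.retained_genes)


@dataclass
class EnrichmentScore:
    """Log2 odds-ratio association of a pathway with an up or down gene list."""

    pathway: str
    direction: str  # "up" | "down"
    score: float
    a: int  # in list and in pathway
    b: int  # in list, not pathway
    c: int  # pathway, not list
    d: int  # neither


@dataclass
class ConcordanceResult:
    """Transcript-protein log-ratio agreement."""

    n_matched: int
    matched_fraction: float
    r_squared: float


def filter_zonation_module(
    expr: NormalizedMatrix,
    module_genes: GeneSet,
    metadata: SampleMetadata,
    other_sources: list[str] = ("Fib", "PSC", "Chol"),
    fold: float = 2.0,
) -> ZonationModule:
    """Keep module genes enriched more than ``fold``-fold in PHH/liver.

    Enrichment is evaluated as a difference of group means on the normalized
    (approximately log2) scale: a gene is retained when
    mean(PHH/Liver) - mean(pooled other sources) > log2(fold).
    """
    if fold <= 1:
        raise ValidationError("fold threshold must exceed 1")
    meta = metadata.table
    phh = [s for s in expr.sample_ids if meta.loc[s, "cell_source"] == PHH_SOURCE]
    others = [
        s for s in expr.sample_ids if meta.loc[s, "cell_source"] in set(other_sources)
    ]
    if not phh:
        raise ValidationError("no PHH/Liver samples in matrix")
    missing_sources = set(other_sources) - set(meta.loc[others, "cell_source"])
    if missing_sources:
        raise ValidationError(f"no samples for source(s): {sorted(missing_sources)}")
    present = [g for g in expr.gene_ids if g in module_genes.gene_ids]
    if not present:
        raise ValidationError(
            f"no gene of module {module_genes.name!r} present in the matrix"
        )
    sub = expr.data.loc[present]
    enrich = sub[phh].mean(axis=1) - sub[others].mean(axis=1)
    retained = frozenset(enrich.index[enrich > np.log2(fold)])
    return ZonationModule(
        name=module_genes.name,
        input_genes=frozenset(module_genes.gene_ids),
        retained_genes=retained,
        fold_threshold=fold,
        enrichment=enrich,
    )


def select_de_genes(
    table: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 1.0
) -> tuple[list[str], list[str]]:
    """Split a DE table into up/down gene lists at strict thresholds.

    up: padj < padj_max and lfc > lfc_min; down: padj < padj_max and
    lfc < -lfc_min.  The table needs columns ``gene``, ``lfc``, ``padj``.
    """
    for col in ("gene", "lfc", "padj"):
        if col not in table.columns:
            raise FormatError(f"DE table missing column {col!r}")
    sig = table[table["padj"] < padj_max]
    up = sig.loc[sig["lfc"] > lfc_min, "gene"].tolist()
    down = sig.loc[sig["lfc"] < -lfc_min, "gene"].tolist()
    return up, down


def _odds_table(genes: set[str], pathway: set[str], universe: set[str]):
    a = len(genes & pathway)
    b = len(genes - pathway)
    c = len(pathway - genes)
    d = len(universe) - a - b - c
    return a, b, c, d


def enrichment_odds_scores(
    up: list[str],
    down: list[str],
    universe: list[str],
    pathways: list[GeneSet],
) -> list[EnrichmentScore]:
    """Log2 odds (up) and log2 inverse-odds (down) pathway enrichment.

    Per pathway a 2x2 table over the universe is formed for each list; the
    up score is log2((a*d)/(b*c)) and the down score log2((b*c)/(a*d)).
    When any cell is zero, 0.5 is added to every cell (Haldane-Anscombe) so
    scores stay finite.  Pathways disjoint from the universe are skipped
    with a warning.
    """
    uni = set(universe)
    up_set, down_set = set(up), set(down)
    if not up_set <= uni or not down_set <= uni:
        raise ValidationError("up/down lists must be subsets of the universe")
    scores: list[EnrichmentScore] = []
    for pw in pathways:
        members = set(pw.gene_ids) & uni
        if not members:
            warnings.warn(f"pathway {pw.name!r} shares no genes with the universe")
            continue
        for direction, genes in (("up", up_set), ("down", down_set)):
            a, b, c, d = _odds_table(genes, members, uni)
            aa, bb, cc, dd = (
                (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
                if min(a, b, c, d) == 0
                else (a, b, c, d)
            )
            log_or = np.log2((aa * dd) / (bb * cc))
            score = log_or if direction == "up" else -log_or
            scores.append(
                EnrichmentScore(
                    pathway=pw.name, direction=direction, score=float(score),
                    a=a, b=b, c=c, d=d,
                )
            )
    return scores


def transcript_protein_concordance(
    tx_ratios: pd.Series,
    protein_ratios: pd.Series,
    id_map: pd.Series,
) -> ConcordanceResult:
    """Pearson R^2 between transcript and protein log-ratios.

    ``id_map`` maps protein identifiers to gene identifiers; proteins whose
    identifier maps to more than one gene are dropped so every matched pair
    is unique.  The matched fraction is relative to the protein table.
    """
    counts = id_map.groupby(level=0).nunique()
    ambiguous = set(counts.index[counts > 1])
    usable = id_map[~id_map.index.isin(ambiguous)]
    pairs = []
    for prot, gene in usable.items():
        if prot in protein_ratios.index and gene in tx_ratios.index:
            pairs.append((tx_ratios[gene], protein_ratios[prot]))
    if len(pairs) < 3:
        raise ValidationError(f"only {len(pairs)} matched pairs; need >= 3")
    x, y = np.array(pairs).T
    r, _ = stats.pearsonr(x, y)
    return ConcordanceResult(
        n_matched=len(pairs),
        matched_fraction=len(pairs) / len(protein_ratios),
        r_squared=float(r**2),
    )
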