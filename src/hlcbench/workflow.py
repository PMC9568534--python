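"""End-to-end workflows: the full comparison run and the add-dataset gate.

``run_compare`` executes merge -> size factors -> VST -> quantile
normalization -> per-gene-set distances/DBS -> PCA -> clustering and can
write every artifact (with provenance headers) to an output directory,
including a training bundle for later dataset additions.

``run_add_dataset`` takes a new study's counts plus metadata, restricts to
the genes shared with training, projects the samples through the frozen
quantile reference, applies the PHH/liver compatibility gate, and — gated or
not, but flagged — scores the query samples against the stored PHH benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ValidationError
from .classify import ClassifierModel, GateDecision, gate_dataset, train_classifier
from .compare import (
    DBSResult,
    PcaResult,
    center_rows_log2fc,
    dbs_scores,
    distance_matrix,
    hierarchical_cluster,
    pca_top_variance,
)
from .io import (
    CountMatrix,
    GeneSet,
    SampleMetadata,
    merge_studies,
    strip_gene_versions,
    write_sample_metadata,
)
from .normalize import (
    NormalizationReference,
    NormalizedMatrix,
    normalize_counts,
    project_counts,
)


def _provenance_header(seed: int, **params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# hlcbench v{__version__} seed={seed} {kv}".rstrip()


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.6g")


def filter_samples(
    metadata: SampleMetadata,
    cell_source: Sequence[str] | None = None,
    min_duration: float | None = None,
    max_duration: float | None = None,
    expandable: str | None = None,
    keep_controls: bool = True,
) -> list[str]:
    """Sample ids passing the property filters; PHH controls are always kept."""
    t = metadata.table
    mask = pd.Series(True, index=t.index)
    if cell_source is not None:
        mask &= t["cell_source"].isin(set(cell_source))
    if min_duration is not None or max_duration is not None:
        dur = pd.to_numeric(t["culture_duration"], errors="coerce")
        if min_duration is not None:
            mask &= dur >= min_duration
        if max_duration is not None:
            mask &= dur <= max_duration
    if expandable is not None:
        mask &= t["expandable"] == expandable
    kept = set(t.index[mask])
    if keep_controls:
        kept |= set(metadata.phh_controls())
    return [s for s in t.index if s in kept]


@dataclass
class CompareBundle:
    """Everything a comparison run produces, ready to query or write out."""

    normalized: NormalizedMatrix
    reference: NormalizationReference
    metadata: SampleMetadata
    dbs: dict[str, DBSResult]
    pca: PcaResult
    newick: str
    centered: pd.DataFrame
    model: ClassifierModel | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = _provenance_header(self.seed, **self.params)
        written: list[Path] = []

        def _note(path: Path) -> Path:
            written.append(path)
            return path

        _write_tsv(
            self.normalized.data,
            _note(outdir / "normalized_matrix.tsv"),
            header,
            "gene_id",
        )
        write_sample_metadata(self.metadata, _note(outdir / "metadata.tsv"))
        for name, res in self.dbs.items():
            safe = name.replace("/", "-").replace(" ", "_")
            _write_tsv(
                res.pairwise.set_index("sample_id"),
                _note(outdir / f"dbs_pairwise_{safe}.tsv"),
                header + f" gene_set={name} max_phh={res.max_phh:.6g}",
                "sample_id",
            )
            _write_tsv(
                res.median_dbs.to_frame(),
                _note(outdir / f"dbs_median_{safe}.tsv"),
                header + f" gene_set={name}",
                "sample_id",
            )
        var_line = ",".join(f"{v:.6g}" for v in self.pca.variance_fraction)
        _write_tsv(
            self.pca.coordinates,
            _note(outdir / "pca_coordinates.tsv"),
            header + f"\n# variance_fraction={var_line}",
            "sample_id",
        )
        _note(outdir / "dendrogram.nwk").write_text(header + "\n" + self.newick + "\n")
        _write_tsv(
            self.centered, _note(outdir / "heatmap_matrix.tsv"), header, "gene_id"
        )
        self.reference.save(_note(outdir / "normalization_reference.txt"))
        if self.model is not None:
            self.model.save(_note(outdir / "classifier.joblib"))
        return written


def run_compare(
    matrices: Sequence[CountMatrix],
    metadata: SampleMetadata,
    gene_sets: Sequence[GeneSet] | None = None,
    n_top_genes: int = 5000,
    seed: int = 0,
    strip_versions: bool = True,
    sample_filter: Sequence[str] | None = None,
    train_identity_model: bool = False,
    size_factor_fallback: str = "error",
) -> CompareBundle:
    """Run the full cross-study comparison pipeline.

    ``sample_filter`` (from :func:`filter_samples`) restricts the analysis
    to selected samples; PHH/liver controls must remain present.  When
    ``train_identity_model`` is set, a cell-source random forest is trained
    on the normalized matrix so the bundle can gate future datasets.
    """
    merged, _ = merge_studies(list(matrices), strip_versions=strip_versions)
    keep = [s for s in merged.sample_ids if s in set(metadata.sample_ids)]
    if sample_filter is not None:
        keep = [s for s in keep if s in set(sample_filter)]
    if not keep:
        raise ValidationError("no samples left after filtering")
    merged = CountMatrix(merged.data[keep])
    meta = metadata.subset(keep)
    if not meta.phh_controls():
        raise ValidationError("metadata must include >= 1 PHH/Liver control")

    normalized, reference = normalize_counts(
        merged, size_factor_fallback=size_factor_fallback
    )
    dbs: dict[str, DBSResult] = {}
    dist_all = distance_matrix(normalized)
    dbs["all_genes"] = dbs_scores(dist_all, meta)
    for gs in gene_sets or []:
        dbs[gs.name] = dbs_scores(distance_matrix(normalized, gs), meta)
    pca = pca_top_variance(normalized, n_top=n_top_genes)
    newick = hierarchical_cluster(normalized)
    centered = center_rows_log2fc(normalized)
    model = None
    if train_identity_model:
        labels = meta.table["cell_source"]
        model = train_classifier(
            normalized, labels, n_top_genes=n_top_genes, seed=seed
        )
    return CompareBundle(
        normalized=normalized,
        reference=reference,
        metadata=meta,
        dbs=dbs,
        pca=pca,
        newick=newick,
        centered=centered,
        model=model,
        seed=seed,
        params={"n_top_genes": n_top_genes, "strip_versions": strip_versions},
    )


@dataclass
class TrainingBundle:
    """Frozen training state needed to admit and score new datasets."""

    normalized: NormalizedMatrix
    reference: NormalizationReference
    metadata: SampleMetadata
    model: ClassifierModel

    @classmethod
    def from_compare(cls, bundle: CompareBundle) -> "TrainingBundle":
        if bundle.model is None:
            raise ValidationError(
                "comparison bundle has no identity model; rerun with "
                "train_identity_model=True"
            )
        return cls(
            normalized=bundle.normalized,
            reference=bundle.reference,
            metadata=bundle.metadata,
            model=bundle.model,
        )

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.normalized.data.to_csv(
            outdir / "training_normalized.tsv", sep="\t", index_label="gene_id"
        )
        write_sample_metadata(self.metadata, outdir / "training_metadata.tsv")
        self.reference.save(outdir / "normalization_reference.txt")
        self.model.save(outdir / "classifier.joblib")

    @classmethod
    def load(cls, outdir: str | Path) -> "TrainingBundle":
        outdir = Path(outdir)
        data = pd.read_csv(
            outdir / "training_normalized.tsv", sep="\t", index_col=0, comment="#"
        )
        from .io import read_sample_metadata

        return cls(
            normalized=NormalizedMatrix(data, ["loaded from training bundle"]),
            reference=NormalizationReference.load(
                outdir / "normalization_reference.txt"
            ),
            metadata=read_sample_metadata(outdir / "training_metadata.tsv"),
            model=ClassifierModel.load(outdir / "classifier.joblib"),
        )


@dataclass
class AddDatasetResult:
    """Gate verdict plus benchmark scores for the new dataset's samples."""

    gate: GateDecision
    query_scores: pd.Series  # median DBS per query sample (all genes shared)
    dbs: DBSResult
    n_shared_genes: int


def run_add_dataset(
    query_counts: CountMatrix,
    query_metadata: SampleMetadata,
    training: TrainingBundle,
    threshold: float = 0.45,
    strip_versions: bool = True,
    size_factor_fallback: str = "error",
    dataset_id: str = "query",
) -> AddDatasetResult:
    """Gate a new dataset and score its samples against the stored benchmark.

    The query must contain PHH/liver control samples.  Scores are computed
    even for an incompatible dataset (the gate verdict travels with them) so
    users can inspect what a rejected dataset would have looked like.
    """
    if not query_metadata.phh_controls():
        raise ValidationError(
            "query has no PHH/Liver controls; new datasets should always "
            "include PHH/liver control samples"
        )
    qdf = query_counts.data
    if strip_versions:
        qdf = qdf.set_axis(strip_gene_versions(qdf.index), axis=0)
    shared = sorted(set(qdf.index) & set(training.normalized.gene_ids))
    if len(shared) < 2:
        raise ValidationError("query shares fewer than 2 genes with training")
    query = CountMatrix(qdf.loc[shared])
    projected = project_counts(
        query, training.reference, size_factor_fallback=size_factor_fallback
    )
    gate = gate_dataset(
        training.model,
        projected,
        query_metadata,
        threshold=threshold,
        dataset_id=dataset_id,
    )
    combined = pd.concat(
        [training.normalized.data.loc[shared], projected.data], axis=1
    )
    combined_meta = SampleMetadata(
        pd.concat([training.metadata.table, query_metadata.table])
    )
    norm = NormalizedMatrix(combined, ["training + projected query on shared genes"])
    # query samples are scored against the *training* benchmark only
    bench_meta = combined_meta.table.copy()
    query_ids = set(query_metadata.sample_ids)
    is_query = bench_meta.index.isin(query_ids)
    bench_meta.loc[is_query, "role"] = "query"
    res = dbs_scores(distance_matrix(norm), SampleMetadata(bench_meta))
    scores = res.median_dbs.loc[[s for s in res.median_dbs.index if s in query_ids]]
    return AddDatasetResult(
        gate=gate, query_scores=scores, dbs=res, n_shared_genes=len(shared)
    )
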