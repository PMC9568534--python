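"""Joint normalization of cross-study count matrices.

The pipeline follows the standard bulk RNA-seq route to a comparable
expression scale: median-of-ratios size factors, a parametric
dispersion-mean trend alpha(mu) = a1/mu + alpha_inf fitted on gene-wise
method-of-moments dispersions, the closed-form variance-stabilizing
transformation implied by that trend (approximately log2 for large counts),
and finally quantile normalization so every sample shares one marginal
distribution.  A frozen quantile reference lets new query samples be
projected onto the training distribution without re-normalizing (and thereby
shifting) the stored benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._errors import FitError, ValidationError
from .io import CountMatrix

_CLAMP = 1e-8


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scale factors (all positive)."""

    factors: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValidationError("size factors must be positive and finite")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])


@dataclass
class DispersionTrend:
    """Parametric dispersion-mean trend alpha(mu) = a1/mu + alpha_inf.

    ``alpha_inf`` is the asymptotic (high-expression) dispersion; ``a1``
    captures extra-Poisson spread at low means.  Both are clamped to 1e-8.
    """

    alpha_inf: float
    a1: float
    n_genes_used: int
    converged: bool = True

    def __post_init__(self) -> None:
        self.alpha_inf = float(max(self.alpha_inf, _CLAMP))
        self.a1 = float(max(self.a1, _CLAMP))

    def alpha(self, mu: np.ndarray) -> np.ndarray:
        return self.a1 / np.asarray(mu, float) + self.alpha_inf


@dataclass
class NormalizedMatrix:
    """Gene-by-sample expression on an approximately log2 scale."""

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("normalized matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class NormalizationReference:
    """Frozen parameters needed to project query samples onto a training scale."""

    size_factor_geomean: float
    trend: DispersionTrend
    quantile_profile: np.ndarray  # sorted reference values, length = n genes

    def save(self, path: str | Path) -> None:
        lines = [
            f"size_factor_geomean\t{self.size_factor_geomean:.10g}",
            f"alpha_inf\t{self.trend.alpha_inf:.10g}",
            f"a1\t{self.trend.a1:.10g}",
            f"n_genes_used\t{self.trend.n_genes_used}",
            f"converged\t{int(self.trend.converged)}",
            "quantile_profile\t" + ",".join(f"{v:.10g}" for v in self.quantile_profile),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationReference":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                key, _, value = line.partition("\t")
                kv[key] = value
        return cls(
            size_factor_geomean=float(kv["size_factor_geomean"]),
            trend=DispersionTrend(
                alpha_inf=float(kv["alpha_inf"]),
                a1=float(kv["a1"]),
                n_genes_used=int(kv["n_genes_used"]),
                converged=bool(int(kv["converged"])),
            ),
            quantile_profile=np.array(
                [float(v) for v in kv["quantile_profile"].split(",")]
            ),
        )


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def compute_size_factors(
    counts: CountMatrix, fallback: str = "error"
) -> SizeFactors:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Only genes with a positive geometric mean (i.e. nonzero in every sample)
    enter the median.  When no such gene exists, ``fallback="positive"``
    computes the pseudo-reference from positive counts only; the default is
    an error pointing at that flag.
    """
    k = counts.counts().astype(float)
    if k.shape[1] < 1:
        raise ValidationError("need at least one sample")
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    all_positive = np.isfinite(logk).all(axis=1)
    if all_positive.any():
        log_ref = logk[all_positive].mean(axis=1)
        # median of the ratios themselves (not of their logs): for an even
        # gene count the two conventions differ at the averaging step
        s = np.median(np.exp(logk[all_positive] - log_ref[:, None]), axis=0)
    elif fallback == "positive":
        any_positive = np.isfinite(logk).any(axis=1)
        if not any_positive.any():
            raise ValidationError("all counts are zero; size factors undefined")
        lk = logk[any_positive]
        log_ref = np.nanmean(np.where(np.isfinite(lk), lk, np.nan), axis=1)
        s = np.empty(k.shape[1])
        for j in range(k.shape[1]):
            ratios = lk[:, j] - log_ref
            ratios = ratios[np.isfinite(ratios)]
            if ratios.size == 0:
                raise ValidationError(f"sample {counts.sample_ids[j]!r} has no counts")
            s[j] = np.median(np.exp(ratios))
    else:
        raise ValidationError(
            "no gene has positive counts in every sample; pass "
            "fallback='positive' to use a positive-counts pseudo-reference"
        )
    return SizeFactors(pd.Series(s, index=counts.sample_ids, name="size_factor"))


# ---------------------------------------------------------------------------
# dispersion trend
# ---------------------------------------------------------------------------


def genewise_dispersions(
    counts: CountMatrix, size_factors: SizeFactors
) -> pd.DataFrame:
    """Method-of-moments dispersion per gene on size-factor-normalized counts.

    Returns columns ``mean`` and ``alpha_hat`` where
    alpha_hat = max((var - mean) / mean^2, 0).
    """
    s = size_factors.factors.loc[counts.sample_ids].to_numpy()
    norm = counts.counts() / s[None, :]
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mean > 0, (var - mean) / mean**2, 0.0)
    alpha = np.maximum(alpha, 0.0)
    return pd.DataFrame({"mean": mean, "alpha_hat": alpha}, index=counts.gene_ids)


def fit_dispersion_trend(
    counts: CountMatrix,
    size_factors: SizeFactors,
    min_mean: float = 1.0,
    max_iter: int = 50,
) -> DispersionTrend:
    """Fit alpha(mu) = a1/mu + alpha_inf by iterative Gamma-GLM regression.

    Gene-wise moment dispersions with mean normalized count > ``min_mean``
    and alpha_hat > 0 are regressed on 1/mean with a Gamma family and
    identity link; genes whose dispersion deviates more than 15-fold (or
    below 1e-4-fold) from the current trend are dropped and the fit repeated
    until the coefficients stabilize.  This mirrors the standard parametric
    dispersion-trend procedure for bulk RNA-seq.
    """
    if counts.shape[1] < 2:
        raise FitError("dispersion fitting needs at least two samples")
    disp = genewise_dispersions(counts, size_factors)
    usable = disp[(disp["mean"] > min_mean) & (disp["alpha_hat"] > 0)]
    if len(usable) < 10:
        raise FitError(
            f"only {len(usable)} genes with mean > {min_mean} and positive "
            "moment dispersion; need >= 10"
        )
    means = usable["mean"].to_numpy()
    alphas = usable["alpha_hat"].to_numpy()

    keep = np.ones(len(usable), bool)
    coef = np.array([0.1, 1.0])  # (alpha_inf, a1)
    converged = False
    for _ in range(max_iter):
        X = np.column_stack([np.ones(keep.sum()), 1.0 / means[keep]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                alphas[keep],
                X,
                family=sm.families.Gamma(link=sm.families.links.Identity()),
            )
            try:
                res = model.fit(start_params=np.maximum(coef, _CLAMP))
            except Exception:
                res = model.fit()
        new_coef = np.maximum(res.params, _CLAMP)
        fitted = new_coef[0] + new_coef[1] / means
        ratio = alphas / fitted
        new_keep = (ratio < 15) & (ratio > 1e-4)
        if new_keep.sum() < 10:
            new_keep = keep
        delta = np.abs(np.log(new_coef) - np.log(np.maximum(coef, _CLAMP))).max()
        coef = new_coef
        if delta < 1e-6 and (new_keep == keep).all():
            converged = True
            break
        keep = new_keep
    if not converged:
        warnings.warn("dispersion trend fit did not converge; using last iterate")
    return DispersionTrend(
        alpha_inf=coef[0], a1=coef[1], n_genes_used=int(keep.sum()), converged=converged
    )


# ---------------------------------------------------------------------------
# variance-stabilizing transformation
# ---------------------------------------------------------------------------


def vst_transform(x: np.ndarray, trend: DispersionTrend) -> np.ndarray:
    """Closed-form VST for the trend's NB variance v(mu) = mu(1+a1) + alpha_inf mu^2.

    The transform is the antiderivative of 1/sqrt(v), rescaled so that it
    approaches log2 for large counts: u(2x) - u(x) -> 1.
    """
    x = np.asarray(x, float)
    a1, ai = trend.a1, trend.alpha_inf
    return np.log2(
        (1.0 + a1 + 2.0 * ai * x + 2.0 * np.sqrt(ai * x * (1.0 + a1 + ai * x)))
        / (4.0 * ai)
    )


def apply_vst(
    counts: CountMatrix, size_factors: SizeFactors, trend: DispersionTrend
) -> NormalizedMatrix:
    """Variance-stabilize size-factor-normalized counts via the fitted trend.

    Falls back to log2(x + 0.5) when the asymptotic dispersion sits at the
    clamp (no usable quadratic variance term).
    """
    s = size_factors.factors.loc[counts.sample_ids].to_numpy()
    x = counts.counts() / s[None, :]
    provenance = [
        "size_factors: median-of-ratios",
        f"vst: alpha_inf={trend.alpha_inf:.6g}, a1={trend.a1:.6g}, "
        f"n_genes_used={trend.n_genes_used}",
    ]
    if trend.alpha_inf <= _CLAMP * (1 + 1e-9):
        values = np.log2(x + 0.5)
        provenance.append("vst: degenerate trend, fell back to log2(x + 0.5)")
    else:
        values = vst_transform(x, trend)
    df = pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids)
    return NormalizedMatrix(df, provenance)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def _map_column_to_profile(col: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Assign each value the profile value at its rank; ties get the mean of
    the profile values spanning their tied positions."""
    n = col.size
    order = np.argsort(col, kind="mergesort")
    out = np.empty(n)
    sorted_vals = col[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        out[order[i : j + 1]] = profile[i : j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(
    matrix: NormalizedMatrix,
    reference: NormalizationReference | np.ndarray | None = None,
) -> NormalizedMatrix:
    """Force identical marginal distributions across samples.

    Without a reference this is classic quantile normalization: each column's
    rank-ordered values are replaced by the across-column mean of sorted
    values at that rank.  With a frozen reference profile, each column is
    mapped onto the reference quantiles instead (linear interpolation when
    the column is longer than the profile), which projects query samples
    onto the training distribution without touching it.
    """
    values = matrix.data.to_numpy()
    if values.shape[1] < 1:
        raise ValidationError("need at least one column")
    if reference is None:
        profile = np.sort(values, axis=0).mean(axis=1)
        prov = "quantile: classic (cross-column rank means)"
    else:
        profile = (
            reference.quantile_profile
            if isinstance(reference, NormalizationReference)
            else np.asarray(reference, float)
        )
        n = values.shape[0]
        if n < 2:
            raise ValidationError(
                f"column has {n} values; projecting onto a reference profile "
                "needs at least 2"
            )
        if n != profile.size:
            # query restricted to shared genes: interpolate the frozen
            # quantile profile to the column's rank grid
            p_col = np.linspace(0.0, 1.0, n)
            p_ref = np.linspace(0.0, 1.0, profile.size)
            profile = np.interp(p_col, p_ref, profile)
        prov = "quantile: projected onto frozen reference profile"
    out = np.column_stack(
        [_map_column_to_profile(values[:, j], profile) for j in range(values.shape[1])]
    )
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return NormalizedMatrix(df, [*matrix.provenance, prov])


# ---------------------------------------------------------------------------
# end-to-end helpers
# ---------------------------------------------------------------------------


def normalize_counts(
    counts: CountMatrix, size_factor_fallback: str = "error"
) -> tuple[NormalizedMatrix, NormalizationReference]:
    """Run size factors -> trend -> VST -> quantile normalization jointly.

    Returns the normalized matrix and a frozen reference capturing the trend
    parameters and quantile profile for later query projection.
    """
    sf = compute_size_factors(counts, fallback=size_factor_fallback)
    trend = fit_dispersion_trend(counts, sf)
    vst = apply_vst(counts, sf, trend)
    profile = np.sort(vst.data.to_numpy(), axis=0).mean(axis=1)
    normalized = quantile_normalize(vst)
    reference = NormalizationReference(
        size_factor_geomean=float(np.exp(np.log(sf.factors).mean())),
        trend=trend,
        quantile_profile=profile,
    )
    return normalized, reference


def project_counts(
    counts: CountMatrix,
    reference: NormalizationReference,
    size_factor_fallback: str = "error",
) -> NormalizedMatrix:
    """Normalize query counts onto a frozen training reference.

    Query size factors are estimated within the query (median of ratios),
    the frozen trend's VST is applied, and columns are mapped onto the
    frozen quantile profile.
    """
    sf = compute_size_factors(counts, fallback=size_factor_fallback)
    vst = apply_vst(counts, sf, reference.trend)
    return quantile_normalize(vst, reference=reference)


def provenance_of(matrix: NormalizedMatrix) -> list[str]:
    return list(matrix.provenance)
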