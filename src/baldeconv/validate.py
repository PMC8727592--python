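"""Validation of proportion estimates against known compositions.

Covers the comparisons used to benchmark a methylation-derived composition
against flow cytometry or known mixture recipes: rescaling cytometry
proportions over the DNA-bearing cell types, mean squared error by cell
type or by subject, Bland-Altman agreement, a fully-methylated /
fully-unmethylated invariant-probe consistency check, a pool-size versus
variance regression, and a classical MDS diagnostic.

All error metrics are computed on the fraction (0-1) scale regardless of
the scale the inputs arrive on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import (
    AlignmentError,
    BetaMatrix,
    ProportionTable,
    SampleSheet,
    ValidationError,
)


def scale_flow_proportions(unscaled):
    """Renormalise cytometry percents over the profiled cell types.

    Cytometry counts every event, including DNA-free cells (typically red
    blood cells) that contribute no methylation signal. Dividing each of
    the four profiled cell types' percentages by their sum puts the flow
    truth on the same footing as a methylation-based estimate. Accepts a
    vector (one sample) or a samples x cell-types frame; output sums to 100
    per sample.
    """
    if isinstance(unscaled, pd.DataFrame):
        arr = unscaled.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("flow proportions must be nonnegative")
        sums = arr.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ValidationError("a sample has all-zero flow proportions")
        return pd.DataFrame(
            arr / sums * 100.0, index=unscaled.index, columns=unscaled.columns
        )
    arr = np.asarray(unscaled, dtype=float)
    if (arr < 0).any():
        raise ValidationError("flow proportions must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValidationError("all-zero flow proportions cannot be scaled")
    scaled = arr / total * 100.0
    if isinstance(unscaled, pd.Series):
        return pd.Series(scaled, index=unscaled.index)
    return scaled


def _aligned_fraction_frames(
    truth: ProportionTable, estimate: ProportionTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    t = truth.as_fraction().data
    e = estimate.as_fraction().data
    if set(t.index) != set(e.index) or set(t.columns) != set(e.columns):
        raise AlignmentError("truth and estimate tables do not share samples/cell types")
    return t, e.loc[t.index, t.columns]


def mse(
    truth: ProportionTable, estimate: ProportionTable, by: str = "cell_type"
) -> pd.Series:
    """Mean squared error between proportions, on the fraction^2 scale.

    ``by='cell_type'`` averages over samples per cell type; ``by='subject'``
    averages over cell types per sample.
    """
    t, e = _aligned_fraction_frames(truth, estimate)
    sq = (e - t) ** 2
    if by == "cell_type":
        return sq.mean(axis=0)
    if by == "subject":
        return sq.mean(axis=1)
    raise ValidationError(f"unknown axis {by!r}; use 'cell_type' or 'subject'")


@dataclass
class BlandAltman:
    """Per-pair means/differences with bias and 95% limits of agreement."""

    pairs: pd.DataFrame  # sample, cell_type, mean, difference
    summary: pd.DataFrame  # per cell type (+ overall): bias, sd, lo, hi


def bland_altman(truth: ProportionTable, estimate: ProportionTable) -> BlandAltman:
    """Bland-Altman agreement between truth and estimate (fraction scale).

    difference = estimate - truth; bias is the mean difference and the
    limits of agreement are bias +/- 1.96 sd of the differences.
    """
    t, e = _aligned_fraction_frames(truth, estimate)
    long = pd.DataFrame(
        {
            "sample_id": np.repeat(t.index.to_numpy(), len(t.columns)),
            "cell_type": np.tile(t.columns.to_numpy(), len(t.index)),
            "mean": ((t + e) / 2.0).to_numpy().ravel(),
            "difference": (e - t).to_numpy().ravel(),
        }
    )

    def _summarise(diff: np.ndarray) -> dict:
        bias = float(np.mean(diff))
        sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
        return {"bias": bias, "sd": sd, "lo": bias - 1.96 * sd, "hi": bias + 1.96 * sd}

    rows = {
        ct: _summarise(long.loc[long["cell_type"] == ct, "difference"].to_numpy())
        for ct in t.columns
    }
    rows["overall"] = _summarise(long["difference"].to_numpy())
    return BlandAltman(long, pd.DataFrame(rows).T)


@dataclass
class InvariantProbeCheck:
    """Probes methylation-invariant across all purified cell types.

    ``side`` is "high" (mean beta >= hi in every cell type) or "low"
    (<= lo in every cell type). ``consistency`` gives, per mixture sample,
    the fraction of invariant probes staying on the same side of 0.5 — high
    values argue that the mixture contains no unprofiled *nucleated* cells.
    """

    side: pd.Series  # probe_id -> "high" | "low"
    mixture_means: pd.DataFrame  # invariant probes x mixture samples
    consistency: pd.Series  # per mixture sample

    @property
    def probe_ids(self) -> list[str]:
        return list(self.side.index)


def invariant_probe_check(
    reference_beta: BetaMatrix,
    sample_sheet: SampleSheet,
    mixture_beta: BetaMatrix,
    hi: float = 0.95,
    lo: float = 0.05,
) -> InvariantProbeCheck:
    """Find probes near-fully (un)methylated in every sorted cell type and
    check they stay so in the mixtures."""
    type_means = pd.DataFrame(
        {
            ct: reference_beta.data[
                [s for s in sample_sheet.samples_of(ct)
                 if s in set(reference_beta.sample_ids)]
            ].mean(axis=1, skipna=True)
            for ct in sample_sheet.cell_types
        }
    )
    high = (type_means >= hi).all(axis=1)
    low = (type_means <= lo).all(axis=1)
    side = pd.concat(
        [
            pd.Series("high", index=type_means.index[high]),
            pd.Series("low", index=type_means.index[low]),
        ]
    )
    common = [p for p in side.index if p in set(mixture_beta.probe_ids)]
    side = side.loc[common]
    mix = mixture_beta.data.loc[common]
    if len(common):
        is_high = (side == "high").to_numpy()[:, None]
        same_side = np.where(is_high, mix.to_numpy() > 0.5, mix.to_numpy() < 0.5)
        with_data = ~np.isnan(mix.to_numpy())
        consistency = pd.Series(
            np.sum(same_side & with_data, axis=0) / np.maximum(with_data.sum(axis=0), 1),
            index=mix.columns,
        )
    else:
        consistency = pd.Series(np.nan, index=mixture_beta.sample_ids)
    return InvariantProbeCheck(side, mix, consistency)


@dataclass
class PoolingRegression:
    slope: float
    adj_r_squared: float
    p_value: float
    n_samples: int


def pooling_variance_regression(
    beta: BetaMatrix, sample_sheet: SampleSheet
) -> PoolingRegression:
    """Regress per-sample variance across probes on pool size (OLS).

    A flat relationship indicates pools are representative of their cell
    type regardless of how many individuals contributed.
    """
    ids = [s for s in sample_sheet.sample_ids if s in set(beta.sample_ids)]
    if len(ids) < 3:
        raise ValidationError("need at least 3 pooled samples for the regression")
    sizes = sample_sheet.pool_sizes().loc[ids].astype(float)
    if sizes.nunique() < 2:
        raise ValidationError("pool sizes must vary across samples")
    variances = beta.data[ids].var(axis=0, ddof=1, skipna=True)

    y = variances.to_numpy()
    if np.allclose(y, y[0]):
        # Degenerate: constant response carries no association.
        return PoolingRegression(0.0, 0.0, 1.0, len(ids))
    X = sm.add_constant(sizes.to_numpy())
    fit = sm.OLS(y, X).fit()
    return PoolingRegression(
        slope=float(fit.params[1]),
        adj_r_squared=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]),
        n_samples=len(ids),
    )


@dataclass
class MDSResult:
    coordinates: pd.DataFrame  # samples x dims
    variance_fractions: np.ndarray


def classical_mds(
    beta: BetaMatrix, top_n_variable: int = 1000, n_dims: int = 3
) -> MDSResult:
    """Classical (Torgerson) MDS of samples on the most variable probes.

    Euclidean distances on the ``top_n_variable`` highest-variance probes
    are double-centred and eigendecomposed; purified cell types should
    separate clearly in the leading dimensions.
    """
    n = len(beta.sample_ids)
    if n < 3:
        raise ValidationError("MDS needs at least 3 samples")
    variances = beta.data.var(axis=1, ddof=1, skipna=True)
    top = variances.sort_values(ascending=False).index[: min(top_n_variable, len(variances))]
    mat = beta.data.loc[top].dropna(axis=0, how="any").to_numpy().T  # samples x probes

    sq = np.sum(mat**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (mat @ mat.T)
    d2 = np.clip(d2, 0.0, None)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = np.clip(eigval, 0.0, None)
    n_dims = min(n_dims, n)
    coords = eigvec[:, :n_dims] * np.sqrt(positive[:n_dims])[None, :]
    total = positive.sum()
    fractions = positive[:n_dims] / total if total > 0 else np.zeros(n_dims)
    frame = pd.DataFrame(
        coords,
        index=beta.sample_ids,
        columns=[f"dim{i + 1}" for i in range(n_dims)],
    )
    return MDSResult(frame, fractions)


def validation_report(
    truth: ProportionTable,
    estimate: ProportionTable,
    reference_beta: BetaMatrix | None = None,
    sample_sheet: SampleSheet | None = None,
    mixture_beta: BetaMatrix | None = None,
) -> dict:
    """Assemble the standard validation summary as a JSON-ready dict."""
    ba = bland_altman(truth, estimate)
    report = {
        "mse_by_cell_type": mse(truth, estimate, by="cell_type").to_dict(),
        "mse_by_subject": mse(truth, estimate, by="subject").to_dict(),
        "bland_altman": {
            str(k): {kk: float(vv) for kk, vv in row.items()}
            for k, row in ba.summary.iterrows()
        },
    }
    if reference_beta is not None and sample_sheet is not None and mixture_beta is not None:
        check = invariant_probe_check(reference_beta, sample_sheet, mixture_beta)
        report["invariant_probes"] = {
            "n_probes": len(check.probe_ids),
            "consistency": {k: float(v) for k, v in check.consistency.items()},
        }
    if reference_beta is not None and sample_sheet is not None:
        try:
            pooling = pooling_variance_regression(reference_beta, sample_sheet)
            report["pooling_regression"] = {
                "slope": pooling.slope,
                "adj_r_squared": pooling.adj_r_squared,
                "p_value": pooling.p_value,
                "n_samples": pooling.n_samples,
            }
        except ValidationError:
            pass
    return report
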