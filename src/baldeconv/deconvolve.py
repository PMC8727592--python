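"""Constrained projection of mixture methylation onto a signature matrix.

The mixture model treats an observed beta vector y over the signature
probes as approximately X w, where X is the signature matrix (mean beta of
each signature probe in each purified cell type) and w the cell-type
proportions. Proportions are estimated by least squares under
nonnegativity, optionally with a sum constraint:

    minimise ||y - X w||^2   s.t.  w >= 0  (and sum w <= 1 or = 1 if asked)

The default is nonnegativity only; with an informative signature the
unconstrained-in-sum solution still lands close to the simplex, and the row
sums near one serve as a sanity check on the reference panel.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .datamodel import (
    AlignmentError,
    BetaMatrix,
    ProportionTable,
    SampleSheet,
    ValidationError,
)
from .qc import restrict_to_common_probes
from .signature import (
    MODE_ANY,
    SignatureMatrix,
    build_signature_matrix,
    one_vs_rest_stats,
    select_probes,
)

SUM_NONE = "none"
SUM_LE_ONE = "le_one"
SUM_EQ_ONE = "eq_one"


class PipelineStageError(RuntimeError):
    """A deconvolution pipeline stage failed; the stage name is attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class ProjectionConfig:
    """Constraint and solver settings for the projection."""

    nonnegative: bool = True
    sum_constraint: str = SUM_NONE  # none | le_one | eq_one
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self):
        if self.tol <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.sum_constraint not in (SUM_NONE, SUM_LE_ONE, SUM_EQ_ONE):
            raise ValidationError(f"unknown sum constraint {self.sum_constraint!r}")


def _solve_sum_to_one(X: np.ndarray, y: np.ndarray, nonnegative: bool) -> np.ndarray:
    """Least squares subject to sum(w) = 1 (optionally w >= 0).

    With nonnegativity this is solved by active-set NNLS on a
    penalty-augmented system (a large-weight row enforcing the equality);
    without, by the KKT linear system. Both are deterministic.
    """
    k = X.shape[1]
    if nonnegative:
        rho = 1e6 * max(1.0, float(np.abs(X).max()))
        X_aug = np.vstack([X, rho * np.ones((1, k))])
        y_aug = np.concatenate([y, [rho]])
        w, _ = optimize.nnls(X_aug, y_aug)
        total = w.sum()
        if total > 0:
            w = w / total  # remove the O(1/rho^2) penalty slack exactly
        return w
    # KKT: [[X'X, 1], [1', 0]] [w; lam] = [X'y; 1]
    G = X.T @ X
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = G
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([X.T @ y, [1.0]])
    sol = np.linalg.solve(kkt, rhs)
    return sol[:k]


def _solve_constrained(X: np.ndarray, y: np.ndarray, config: ProjectionConfig) -> np.ndarray:
    """Exact solution of the sum-constrained least-squares problem.

    For ``le_one`` the convex KKT logic applies: if the optimum of the
    sum-unconstrained problem already satisfies sum(w) <= 1 it is the
    answer; otherwise the constraint binds and the problem reduces to
    ``eq_one``.
    """
    if config.sum_constraint == SUM_LE_ONE:
        if config.nonnegative:
            w, _ = optimize.nnls(X, y)
        else:
            w, *_ = np.linalg.lstsq(X, y, rcond=None)
        if w.sum() <= 1.0 + config.tol:
            return np.asarray(w)
    return _solve_sum_to_one(X, y, config.nonnegative)


def project_one(
    sample_beta: pd.Series | np.ndarray,
    signature: SignatureMatrix,
    config: ProjectionConfig | None = None,
) -> pd.Series:
    """Project one mixture sample onto the signature matrix.

    ``sample_beta`` must be indexed by (or ordered as) the signature probes.
    Probes missing in the sample are dropped pairwise from both sides; at
    least as many observations as cell types must remain and the reduced
    design must have full column rank.
    """
    config = config or ProjectionConfig()
    X_frame = signature.mean_beta
    if isinstance(sample_beta, pd.Series):
        missing = set(X_frame.index) - set(sample_beta.index)
        if missing:
            raise AlignmentError(
                f"sample lacks {len(missing)} signature probes, e.g. {sorted(missing)[:3]}"
            )
        y = sample_beta.reindex(X_frame.index).to_numpy(dtype=float)
    else:
        y = np.asarray(sample_beta, dtype=float)
        if y.shape[0] != X_frame.shape[0]:
            raise AlignmentError("sample vector length does not match signature probes")
    X = X_frame.to_numpy(dtype=float)

    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    y, X = y[keep], X[keep]
    k = X.shape[1]
    if X.shape[0] < k:
        raise ValidationError(
            f"only {X.shape[0]} usable signature probes for {k} cell types"
        )
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("signature matrix is rank deficient after missing-drop")

    if config.sum_constraint == SUM_NONE:
        if config.nonnegative:
            w, _ = optimize.nnls(X, y)
        else:
            w, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        w = _solve_constrained(X, y, config)

    if config.sum_constraint == SUM_EQ_ONE and abs(w.sum() - 1.0) > max(config.tol, 1e-6):
        raise ValidationError("solver did not satisfy the sum-to-one constraint")
    return pd.Series(w, index=X_frame.columns, name="weight")


def project_samples(
    mixture_beta: BetaMatrix,
    signature: SignatureMatrix,
    config: ProjectionConfig | None = None,
) -> ProportionTable:
    """Project every column of ``mixture_beta``; rows are samples."""
    sig_probes = set(signature.probe_ids)
    missing = sig_probes - set(mixture_beta.probe_ids)
    if missing:
        raise AlignmentError(
            f"mixture matrix lacks {len(missing)} signature probes"
        )
    rows = {}
    sub = mixture_beta.data.loc[signature.probe_ids]
    for sample in mixture_beta.sample_ids:
        rows[sample] = project_one(sub[sample], signature, config)
    table = pd.DataFrame(rows).T
    table.index.name = "sample_id"
    return ProportionTable(table, scale="fraction")


def estimate_cell_counts(
    mixture_beta: BetaMatrix,
    reference_beta: BetaMatrix,
    sample_sheet: SampleSheet,
    qc_exclusions: set[str] | None = None,
    mode: str = MODE_ANY,
    config: ProjectionConfig | None = None,
    n_any: int = 100,
    n_each: int = 50,
    p_threshold: float = 1e-8,
) -> tuple[ProportionTable, SignatureMatrix]:
    """End-to-end proportion estimation from a custom reference panel.

    Pipeline: drop QC-excluded probes, restrict reference and mixtures to
    common probes, compute one-vs-rest statistics, select signature probes
    in the requested mode, build the signature matrix, and project every
    mixture sample. Returns fraction-scale proportions plus the signature
    (selection metadata attached).
    """
    config = config or ProjectionConfig()
    try:
        if qc_exclusions:
            keep_ref = [p for p in reference_beta.probe_ids if p not in qc_exclusions]
            keep_mix = [p for p in mixture_beta.probe_ids if p not in qc_exclusions]
            reference_beta = reference_beta.restrict_probes(keep_ref)
            mixture_beta = mixture_beta.restrict_probes(keep_mix)
        reference_beta, mixture_beta = restrict_to_common_probes(
            reference_beta, mixture_beta
        )
    except Exception as e:
        raise PipelineStageError("restrict_to_common_probes", e) from e
    try:
        stats = one_vs_rest_stats(reference_beta, sample_sheet)
    except Exception as e:
        raise PipelineStageError("one_vs_rest_stats", e) from e
    try:
        selection = select_probes(
            stats, mode=mode, n_any=n_any, n_each=n_each, p_threshold=p_threshold
        )
    except Exception as e:
        raise PipelineStageError("select_probes", e) from e
    try:
        signature = build_signature_matrix(reference_beta, sample_sheet, selection)
    except Exception as e:
        raise PipelineStageError("build_signature_matrix", e) from e
    try:
        proportions = project_samples(mixture_beta, signature, config)
    except Exception as e:
        raise PipelineStageError("project_samples", e) from e
    return proportions, signature


def aggregate_estimates(
    table: ProportionTable, grouping: Mapping[str, str]
) -> ProportionTable:
    """Sum proportions within supergroups (e.g. T + B + NK -> Lymphocyte).

    ``grouping`` must cover every cell type in the table.
    """
    missing = set(table.cell_types) - set(grouping)
    if missing:
        raise ValidationError(f"grouping does not cover cell types: {sorted(missing)}")
    groups = pd.Series({ct: grouping[ct] for ct in table.cell_types})
    order = list(dict.fromkeys(groups[ct] for ct in table.cell_types))
    summed = table.data.T.groupby(groups).sum(min_count=1).T.loc[:, order]
    return ProportionTable(summed, scale=table.scale, normalized=table.normalized,
                           validate=False)
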