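"""Synthetic methylation data with known cell-type composition.

The generator emulates the study design behind a sorted-cell reference
panel for a mixed tissue: per-cell-type mean beta profiles with planted
hyper-/hypo-methylated signature CpGs on a shared bimodal background,
per-individual sorted samples, equal-mass DNA pools, and noisy mixtures
with Dirichlet-distributed true weights. Mixtures may additionally carry an
*unprofiled* fraction of DNA-free cells (red-blood-cell-like): it dilutes
the composition a cytometer would report, but contributes no methylation
signal, so it never touches the simulated beta values.

Noise model: an observed beta around mean ``m`` is drawn from
``Beta(m * s, (1 - m) * s)`` with precision ``s``, giving variance
``m (1 - m) / (1 + s)``; means are clipped to [0.005, 0.995] before
parameterisation so the Beta parameters stay away from zero. ``s = inf``
returns the means exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_CELL_TYPES,
    ROLE_MIXTURE,
    ROLE_REFERENCE,
    BetaMatrix,
    DetectionPMatrix,
    ProportionTable,
    SampleSheet,
)

#: Dirichlet concentration mirroring the median composition of
#: bronchoalveolar lavage (macrophage-dominant, scarce epithelial cells).
DEFAULT_DIRICHLET_ALPHA = (6.4, 2.4, 0.8, 0.2)

#: Default range for the DNA-free (red-blood-cell-like) fraction, matching
#: cytometry runs that identify roughly half to ninety percent of events.
DEFAULT_UNPROFILED_RANGE = (0.1, 0.5)

_MEAN_CLIP = (0.005, 0.995)


@dataclass
class CellTypeProfiles:
    """Ground-truth per-cell-type mean beta profiles.

    ``signature_map`` records the planted discriminating probes:
    probe id -> (cell type, "hyper" | "hypo").
    """

    cell_types: list[str]
    probe_ids: list[str]
    mean_beta: pd.DataFrame  # probes x cell types
    signature_map: dict[str, tuple[str, str]]

    def planted_probes(self, cell_type: str | None = None) -> list[str]:
        return [
            p
            for p, (ct, _) in self.signature_map.items()
            if cell_type is None or ct == cell_type
        ]


@dataclass
class MixtureTruth:
    """Known composition of simulated mixtures.

    ``true_weights`` covers the profiled cell types only and sums to one per
    sample; ``unprofiled_fraction`` is the DNA-free fraction present in the
    physical sample but invisible to methylation.
    """

    true_weights: ProportionTable
    unprofiled_fraction: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return self.true_weights.sample_ids

    def scaled_flow(self) -> ProportionTable:
        """Cytometry truth renormalised over the profiled cell types (percent)."""
        return self.true_weights.as_percent()

    def original_flow(self) -> ProportionTable:
        """Cytometry truth over all cells, including the DNA-free fraction."""
        frac = self.true_weights.as_fraction().data.mul(
            1.0 - self.unprofiled_fraction, axis=0
        )
        return ProportionTable(frac * 100.0, scale="percent", validate=False)


def _draw_beta_noise(
    means: np.ndarray, precision: float, rng: np.random.Generator
) -> np.ndarray:
    if not np.isfinite(precision):
        return means.copy()
    if precision <= 0:
        raise ValueError("precision must be > 0")
    m = np.clip(means, *_MEAN_CLIP)
    return rng.beta(m * precision, (1.0 - m) * precision)


def generate_profiles(
    n_probes: int,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    n_signature_per_type: int = 60,
    delta: float = 0.5,
    seed: int | None = None,
) -> CellTypeProfiles:
    """Generate ground-truth profiles with planted signature probes.

    Background probes share one bimodal mean across all cell types (equal
    mixture of Beta(0.5, 5) and Beta(5, 0.5)). Each planted hyper probe has
    its own type's mean at least ``delta`` above every other type; hypo
    probes are symmetric. Deterministic given ``seed``.
    """
    cell_types = list(cell_types)
    k = len(cell_types)
    n_planted = k * 2 * n_signature_per_type
    if n_probes < n_planted:
        raise ValueError(
            f"n_probes={n_probes} cannot host {n_planted} planted signature probes"
        )
    if not (0.0 < delta <= 0.9):
        raise ValueError("delta must be in (0, 0.9]")
    rng = np.random.default_rng(seed)

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    low_mode = rng.beta(0.5, 5.0, size=n_probes)
    high_mode = rng.beta(5.0, 0.5, size=n_probes)
    background = np.where(rng.random(n_probes) < 0.5, low_mode, high_mode)
    mean_beta = np.tile(background[:, None], (1, k))

    planted_idx = rng.choice(n_probes, size=n_planted, replace=False)
    signature_map: dict[str, tuple[str, str]] = {}
    pos = 0
    for ct_i, ct in enumerate(cell_types):
        for direction in ("hyper", "hypo"):
            idx = planted_idx[pos : pos + n_signature_per_type]
            pos += n_signature_per_type
            n = len(idx)
            if direction == "hyper":
                others = rng.uniform(0.01, 0.98 - delta, size=n)
                margin = rng.uniform(0.005, 1.0, size=n) * (0.99 - delta - others)
                own = others + delta + np.minimum(margin, 0.99 - delta - others)
            else:
                others = rng.uniform(delta + 0.02, 0.99, size=n)
                margin = rng.uniform(0.005, 1.0, size=n) * (others - delta - 0.01)
                own = others - delta - np.minimum(margin, others - delta - 0.01)
            mean_beta[idx, :] = others[:, None]
            mean_beta[idx, ct_i] = own
            for j in idx:
                signature_map[probe_ids[j]] = (ct, direction)

    frame = pd.DataFrame(
        np.clip(mean_beta, 0.0, 1.0), index=probe_ids, columns=cell_types
    )
    return CellTypeProfiles(cell_types, probe_ids, frame, signature_map)


def sample_individuals(
    profiles: CellTypeProfiles,
    n_per_type: int,
    precision: float = 100.0,
    seed: int | None = None,
) -> tuple[BetaMatrix, SampleSheet]:
    """Draw per-individual sorted-cell samples around the cell-type means.

    Each individual's beta at each probe is ``Beta(m s, (1 - m) s)`` around
    the cell-type mean ``m``, i.e. variance ``m (1 - m) / (1 + s)``.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    rows = []
    for ct in profiles.cell_types:
        means = profiles.mean_beta[ct].to_numpy()
        for j in range(n_per_type):
            sample_id = f"{ct}_ind{j + 1}"
            columns[sample_id] = _draw_beta_noise(means, precision, rng)
            rows.append(
                {"sample_id": sample_id, "role": ROLE_REFERENCE, "cell_type": ct,
                 "pool_size": 1, "batch": "sim"}
            )
    beta = BetaMatrix(
        pd.DataFrame(columns, index=profiles.probe_ids), validate=False
    )
    return beta, SampleSheet(pd.DataFrame(rows))


def pool_samples(
    beta: BetaMatrix,
    sample_sheet: SampleSheet,
    pooling: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
) -> tuple[BetaMatrix, SampleSheet]:
    """Combine individual sorted samples into equal-mass DNA pools.

    Pooling equal DNA masses averages methylation fractions, so each pool
    column is the arithmetic mean of its member columns. All members of a
    pool must share one cell type; the pool's ``pool_size`` is the total
    number of pooled individuals.
    """
    if not isinstance(pooling, Mapping):
        pooling = {f"pool_{i + 1}": group for i, group in enumerate(pooling)}
    columns: dict[str, np.ndarray] = {}
    rows = []
    sizes = sample_sheet.pool_sizes()
    for pool_id, group in pooling.items():
        group = list(group)
        if not group:
            raise ValueError(f"pool {pool_id!r} is empty")
        member_types = {sample_sheet.cell_type_of(s) for s in group}
        if len(member_types) != 1:
            raise ValueError(
                f"pool {pool_id!r} mixes cell types: {sorted(map(str, member_types))}"
            )
        sub = beta.restrict_samples(group)
        columns[pool_id] = np.nanmean(sub.data.to_numpy(), axis=1)
        rows.append(
            {
                "sample_id": pool_id,
                "role": ROLE_REFERENCE,
                "cell_type": member_types.pop(),
                "pool_size": int(sum(sizes.get(s, 1) for s in group)),
                "batch": "sim",
            }
        )
    pooled = BetaMatrix(pd.DataFrame(columns, index=beta.probe_ids), validate=False)
    return pooled, SampleSheet(pd.DataFrame(rows))


def generate_mixtures(
    profiles: CellTypeProfiles,
    n_mixtures: int,
    dirichlet_alpha: Sequence[float] | None = None,
    weights: np.ndarray | Sequence[Sequence[float]] | None = None,
    noise_precision: float = 200.0,
    unprofiled_range: tuple[float, float] = DEFAULT_UNPROFILED_RANGE,
    seed: int | None = None,
) -> tuple[BetaMatrix, MixtureTruth]:
    """Simulate mixed-cell samples with known composition.

    The per-probe mixture mean is the weight-weighted average of the
    cell-type means; the observed beta is drawn around it at
    ``noise_precision``. Explicit ``weights`` (n_mixtures x n_cell_types)
    override the Dirichlet draw and must each sum to one.
    """
    rng = np.random.default_rng(seed)
    k = len(profiles.cell_types)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.ndim == 1:
            w = w[None, :]
        if w.shape != (n_mixtures, k):
            raise ValueError(f"weights must have shape ({n_mixtures}, {k})")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.max(np.abs(w.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("each weight vector must sum to 1 within 1e-6")
    else:
        alpha = np.asarray(
            DEFAULT_DIRICHLET_ALPHA if dirichlet_alpha is None else dirichlet_alpha,
            dtype=float,
        )
        if alpha.shape != (k,):
            raise ValueError(f"dirichlet_alpha must have length {k}")
        w = rng.dirichlet(alpha, size=n_mixtures)

    lo, hi = unprofiled_range
    if not (0.0 <= lo <= hi < 1.0):
        raise ValueError("unprofiled_range must satisfy 0 <= lo <= hi < 1")
    unprofiled = lo + rng.random(n_mixtures) * (hi - lo)

    means = profiles.mean_beta.to_numpy() @ w.T  # probes x mixtures
    observed = _draw_beta_noise(means, noise_precision, rng)
    sample_ids = [f"mix{i + 1}" for i in range(n_mixtures)]
    beta = BetaMatrix(
        pd.DataFrame(observed, index=profiles.probe_ids, columns=sample_ids),
        validate=False,
    )
    truth = MixtureTruth(
        true_weights=ProportionTable(
            pd.DataFrame(w, index=sample_ids, columns=profiles.cell_types),
            scale="fraction",
            normalized=True,
        ),
        unprofiled_fraction=pd.Series(unprofiled, index=sample_ids, name="unprofiled"),
    )
    return beta, truth


def mixture_sample_sheet(truth: MixtureTruth) -> SampleSheet:
    """Sample sheet rows declaring the simulated mixtures as mixtures."""
    rows = [
        {"sample_id": s, "role": ROLE_MIXTURE, "cell_type": None, "pool_size": 1,
         "batch": "sim"}
        for s in truth.sample_ids
    ]
    return SampleSheet(pd.DataFrame(rows))


def simulate_detection_p(
    beta: BetaMatrix, fail_rate: float = 0.0, seed: int | None = None
) -> DetectionPMatrix:
    """Simulate detection p-values: passing entries uniform on [0, 0.005],
    failing entries uniform on (0.01, 1]."""
    if not (0.0 <= fail_rate < 1.0):
        raise ValueError("fail_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = beta.shape
    fails = rng.random(shape) < fail_rate
    passing = rng.uniform(0.0, 0.005, size=shape)
    failing = rng.uniform(0.01, 1.0, size=shape)
    failing = np.nextafter(failing, 2.0)  # open at 0.01, closed at 1
    values = np.where(fails, failing, passing)
    return DetectionPMatrix(
        pd.DataFrame(np.clip(values, 0.0, 1.0), index=beta.probe_ids,
                     columns=beta.sample_ids),
        validate=False,
    )
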