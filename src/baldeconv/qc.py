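"""Sample- and probe-level quality control and normalisation.

The filters follow standard methylation-array practice: samples whose mean
detection p-value exceeds a threshold are dropped first, then probes are
removed if they fail detection in any retained sample or carry an exclusion
flag (SNP at the CpG, sex chromosome, cross-reactive). Removal reasons are
attributed to the first matching cause in that fixed order so the report is
deterministic.

Normalisation is cross-sample quantile normalisation, optionally stratified
by probe design type. It maps each sample onto the mean empirical quantile
function across samples; it is monotone within sample, so ranks are
preserved.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    AlignmentError,
    BetaMatrix,
    DetectionPMatrix,
    ProbeAnnotation,
)

logger = logging.getLogger(__name__)

#: First-cause attribution order for probe removal.
PROBE_REMOVAL_REASONS = ("detection", "snp", "sex", "cross_reactive")


@dataclass
class QCReport:
    """Bookkeeping for one filtering step.

    ``probes_removed`` maps each reason to the probes removed *for that
    reason first*; the reason sets are disjoint and their sizes sum to the
    total number of probes removed.
    """

    samples_input: int = 0
    samples_removed: dict[str, float] = field(default_factory=dict)
    probes_input: int = 0
    probes_removed: dict[str, list[str]] = field(default_factory=dict)
    probes_retained: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def samples_retained(self) -> int:
        return self.samples_input - len(self.samples_removed)

    @property
    def probes_removed_counts(self) -> dict[str, int]:
        return {reason: len(ids) for reason, ids in self.probes_removed.items()}

    def to_dict(self) -> dict:
        return {
            "samples_input": self.samples_input,
            "samples_removed": self.samples_removed,
            "samples_retained": self.samples_retained,
            "probes_input": self.probes_input,
            "probes_removed_counts": self.probes_removed_counts,
            "probes_removed": self.probes_removed,
            "probes_retained": self.probes_retained,
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _aligned_detp(beta: BetaMatrix, detp: DetectionPMatrix) -> pd.DataFrame:
    missing_probes = set(beta.probe_ids) - set(detp.probe_ids)
    missing_samples = set(beta.sample_ids) - set(detp.sample_ids)
    if missing_probes or missing_samples:
        raise AlignmentError(
            "detection p matrix does not cover the beta matrix "
            f"({len(missing_probes)} probes, {len(missing_samples)} samples missing)"
        )
    return detp.data.loc[beta.probe_ids, beta.sample_ids]


def filter_samples_by_detection(
    beta: BetaMatrix, detp: DetectionPMatrix, threshold: float = 0.01
) -> tuple[BetaMatrix, QCReport]:
    """Drop samples whose mean detection p-value exceeds ``threshold``."""
    dp = _aligned_detp(beta, detp)
    mean_p = dp.mean(axis=0, skipna=True)
    removed = mean_p[mean_p > threshold]
    keep = [s for s in beta.sample_ids if s not in set(removed.index)]
    report = QCReport(
        samples_input=len(beta.sample_ids),
        samples_removed={s: float(v) for s, v in removed.items()},
        probes_input=len(beta.probe_ids),
        probes_retained=len(beta.probe_ids),
    )
    for s, v in removed.items():
        logger.warning("removing sample %s (mean detection p %.4g)", s, v)
    return beta.restrict_samples(keep), report


def filter_probes(
    beta: BetaMatrix,
    detp: DetectionPMatrix,
    annotation: ProbeAnnotation | None = None,
    threshold: float = 0.01,
) -> tuple[BetaMatrix, QCReport]:
    """Drop probes failing detection in any retained sample or flagged for
    exclusion. Apply after sample filtering."""
    dp = _aligned_detp(beta, detp)
    failing = (dp > threshold).any(axis=1)

    if annotation is None:
        annotation = ProbeAnnotation(pd.DataFrame(index=pd.Index([], name="probe_id")))
    flags, unannotated = annotation.flags_for(beta.probe_ids)

    report = QCReport(
        samples_input=len(beta.sample_ids),
        probes_input=len(beta.probe_ids),
    )
    if unannotated:
        note = f"{len(unannotated)} probes absent from annotation treated as unflagged"
        report.notes.append(note)
        logger.info(note)

    reason_masks = {
        "detection": failing.to_numpy(),
        "snp": flags["snp_at_cpg"].to_numpy(),
        "sex": flags["on_sex_chromosome"].to_numpy(),
        "cross_reactive": flags["cross_reactive"].to_numpy(),
    }
    assigned = np.zeros(len(beta.probe_ids), dtype=bool)
    probe_index = np.asarray(beta.probe_ids)
    for reason in PROBE_REMOVAL_REASONS:
        mask = reason_masks[reason] & ~assigned
        report.probes_removed[reason] = probe_index[mask].tolist()
        assigned |= reason_masks[reason]
    keep = probe_index[~assigned].tolist()
    report.probes_retained = len(keep)
    return beta.restrict_probes(keep), report


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Map each column to the mean empirical quantile function.

    Missing values are excluded from the quantile computation and stay
    missing; columns with unequal numbers of observed values are handled by
    linear interpolation onto a common quantile grid.
    """
    n_obs = df.notna().sum()
    m = int(n_obs.max())
    if m == 0:
        return df.copy()
    grid = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
    qfuncs = []
    for c in df.columns:
        v = np.sort(df[c].dropna().to_numpy())
        if v.size == 0:
            continue
        if v.size == 1:
            qfuncs.append(np.full_like(grid, v[0]))
        else:
            qfuncs.append(np.interp(grid, np.linspace(0.0, 1.0, v.size), v))
    reference = np.mean(qfuncs, axis=0)

    out = df.copy()
    for c in df.columns:
        col = df[c]
        mask = col.notna()
        n = int(mask.sum())
        if n == 0:
            continue
        ranks = col[mask].rank(method="average").to_numpy()
        q = (ranks - 1.0) / (n - 1.0) if n > 1 else np.array([0.5])
        out.loc[mask, c] = np.interp(q, grid, reference)
    return out


def quantile_normalize(
    beta: BetaMatrix,
    stratify_by_design: bool = False,
    annotation: ProbeAnnotation | None = None,
) -> BetaMatrix:
    """Cross-sample quantile normalisation of a beta matrix.

    With ``stratify_by_design`` and an annotation providing ``design_type``,
    normalisation runs separately within each design stratum (the two EPIC
    probe chemistries have different beta distributions). A single-sample
    matrix is returned unchanged with a warning.
    """
    if len(beta.sample_ids) < 2:
        warnings.warn("quantile normalisation skipped: fewer than 2 samples")
        return BetaMatrix(beta.data.copy(), validate=False)
    if stratify_by_design and annotation is not None:
        design = annotation.design_types(beta.probe_ids).fillna("__unknown__")
        pieces = []
        for _, idx in design.groupby(design).groups.items():
            pieces.append(_quantile_normalize_frame(beta.data.loc[idx]))
        normalized = pd.concat(pieces).loc[beta.probe_ids]
    else:
        normalized = _quantile_normalize_frame(beta.data)
    return BetaMatrix(normalized.clip(0.0, 1.0), validate=False)


def restrict_to_common_probes(
    reference_beta: BetaMatrix, mixture_beta: BetaMatrix
) -> tuple[BetaMatrix, BetaMatrix]:
    """Restrict both matrices to their common probes, in reference order."""
    mixture_set = set(mixture_beta.probe_ids)
    common = [p for p in reference_beta.probe_ids if p in mixture_set]
    if not common:
        raise AlignmentError("reference and mixture matrices share no probes")
    return reference_beta.restrict_probes(common), mixture_beta.restrict_probes(common)
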