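"""Selection of cell-type-discriminating signature probes.

For each cell type, every probe is scored by an equal-variance one-vs-rest
comparison of that type's purified reference samples against all other
reference samples: the F statistic (the square of the pooled two-sample t
statistic, with 1 and n - 2 degrees of freedom) and the mean-beta difference
delta_beta = mean(in type) - mean(rest).

Two selection modes mirror common reference-panel construction options:

* ``both`` — per cell type, the top ``n_each`` hypermethylated
  (delta_beta > 0) and top ``n_each`` hypomethylated (delta_beta < 0)
  probes among those with F-test p below the threshold;
* ``any`` — the top ``n_any`` probes by \\|delta_beta\\| regardless of
  direction, again restricted to significant probes.

The union across cell types, deduplicated, forms the rows of the signature
matrix used as the deconvolution design.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

MODE_ANY = "any"
MODE_BOTH = "both"


@dataclass
class ProbeStats:
    """Per-(cell type, probe) one-vs-rest statistics.

    ``stats`` is a long-format frame with columns ``cell_type``,
    ``probe_id``, ``f_stat``, ``p_value``, ``delta_beta``.
    """

    stats: pd.DataFrame
    cell_types: list[str]

    def for_cell_type(self, cell_type: str) -> pd.DataFrame:
        sub = self.stats[self.stats["cell_type"] == cell_type]
        if sub.empty:
            raise KeyError(f"no statistics for cell type {cell_type!r}")
        return sub.set_index("probe_id")


@dataclass
class SelectionResult:
    """Per-cell-type selections plus the deduplicated union."""

    mode: str
    p_threshold: float
    per_type: dict[str, list[str]]
    union: list[str]
    shortfalls: dict[str, str] = field(default_factory=dict)

    @property
    def per_type_counts(self) -> dict[str, int]:
        return {ct: len(v) for ct, v in self.per_type.items()}


@dataclass
class SignatureMatrix:
    """Signature probes x cell types mean betas: the projection design."""

    mean_beta: pd.DataFrame  # probes x cell types
    metadata: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.mean_beta.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_beta.columns)


def one_vs_rest_stats(reference_beta: BetaMatrix, sample_sheet: SampleSheet) -> ProbeStats:
    """Equal-variance one-vs-rest F statistics for every (cell type, probe).

    Probes with zero pooled variance get ``f_stat = inf, p = 0`` when the
    group means differ and ``f_stat = 0, p = 1`` otherwise. Missing betas
    are dropped per probe; a probe needs at least one observation per group
    and a positive residual degree of freedom, else its stats are missing.
    """
    cell_types = sample_sheet.cell_types
    if len(cell_types) < 2:
        raise ValidationError("need at least 2 cell types for one-vs-rest statistics")
    ref_ids = [s for s in sample_sheet.reference_ids if s in set(reference_beta.sample_ids)]
    for ct in cell_types:
        n_ct = len([s for s in sample_sheet.samples_of(ct) if s in set(ref_ids)])
        if n_ct < 2:
            raise ValidationError(f"cell type {ct!r} has {n_ct} reference samples; need >= 2")
    if len(ref_ids) - max(len(sample_sheet.samples_of(ct)) for ct in cell_types) < 2:
        raise ValidationError("rest group needs at least 2 reference samples")

    data = reference_beta.data[ref_ids]
    blocks = []
    for ct in cell_types:
        in_ids = [s for s in sample_sheet.samples_of(ct) if s in set(ref_ids)]
        out_ids = [s for s in ref_ids if s not in set(in_ids)]
        x1 = data[in_ids].to_numpy()
        x2 = data[out_ids].to_numpy()
        n1 = (~np.isnan(x1)).sum(axis=1).astype(float)
        n2 = (~np.isnan(x2)).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            m1 = np.nanmean(x1, axis=1)
            m2 = np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
        df_resid = n1 + n2 - 2.0
        delta = m1 - m2

        f = np.full(len(data), np.nan)
        p = np.full(len(data), np.nan)
        valid = (n1 >= 1) & (n2 >= 1) & (df_resid >= 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = (ss1 + ss2) / df_resid
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            f_raw = delta**2 / se2
        ok = valid & (se2 > 0)
        f[ok] = f_raw[ok]
        p[ok] = sps.f.sf(f_raw[ok], 1, df_resid[ok])
        degen = valid & (se2 == 0)
        differs = degen & (delta != 0)
        f[differs], p[differs] = np.inf, 0.0
        same = degen & (delta == 0)
        f[same], p[same] = 0.0, 1.0

        blocks.append(
            pd.DataFrame(
                {
                    "cell_type": ct,
                    "probe_id": data.index,
                    "f_stat": f,
                    "p_value": p,
                    "delta_beta": delta,
                }
            )
        )
    return ProbeStats(pd.concat(blocks, ignore_index=True), cell_types)


def _ranked(frame: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking: larger |delta_beta|, then smaller p, then id."""
    key = frame.assign(_absd=frame["delta_beta"].abs())
    return key.sort_values(
        ["_absd", "p_value", "probe_id"], ascending=[False, True, True]
    )


def select_probes(
    stats: ProbeStats,
    mode: str = MODE_ANY,
    n_any: int = 100,
    n_each: int = 50,
    p_threshold: float = 1e-8,
) -> SelectionResult:
    """Select signature probes per cell type and deduplicate the union.

    Candidates are first restricted to F-test p below ``p_threshold``; a
    cell type with no significant candidate raises; shortfalls against the
    requested counts are allowed and recorded.
    """
    if mode not in (MODE_ANY, MODE_BOTH):
        raise ValidationError(f"unknown selection mode {mode!r}")
    per_type: dict[str, list[str]] = {}
    shortfalls: dict[str, str] = {}
    union: list[str] = []
    seen: set[str] = set()
    for ct in stats.cell_types:
        sub = stats.stats[stats.stats["cell_type"] == ct]
        sig = sub[sub["p_value"] < p_threshold]
        if sig.empty:
            raise ValidationError(f"no significant probes for cell type {ct!r}")
        if mode == MODE_ANY:
            chosen = _ranked(sig).head(n_any)["probe_id"].tolist()
            want = n_any
        else:
            hyper = _ranked(sig[sig["delta_beta"] > 0]).head(n_each)["probe_id"].tolist()
            hypo = _ranked(sig[sig["delta_beta"] < 0]).head(n_each)["probe_id"].tolist()
            chosen = hyper + hypo
            want = 2 * n_each
        if len(chosen) < want:
            msg = f"{len(chosen)}/{want} significant probes available"
            shortfalls[ct] = msg
            logger.warning("cell type %s: %s", ct, msg)
        per_type[ct] = chosen
        for p in chosen:
            if p not in seen:
                seen.add(p)
                union.append(p)
    return SelectionResult(mode, p_threshold, per_type, union, shortfalls)


def build_signature_matrix(
    reference_beta: BetaMatrix,
    sample_sheet: SampleSheet,
    selection: SelectionResult | list[str],
) -> SignatureMatrix:
    """Mean beta of each selected probe within each cell type's references."""
    if isinstance(selection, SelectionResult):
        probes = selection.union
        metadata = {
            "mode": selection.mode,
            "p_threshold": selection.p_threshold,
            "per_type_counts": selection.per_type_counts,
            "shortfalls": selection.shortfalls,
        }
    else:
        probes = list(selection)
        metadata = {}
    missing = set(probes) - set(reference_beta.probe_ids)
    if missing:
        raise ValidationError(
            f"selected probes absent from reference beta: {sorted(missing)[:5]}"
        )
    cols = {}
    for ct in sample_sheet.cell_types:
        ids = [s for s in sample_sheet.samples_of(ct) if s in set(reference_beta.sample_ids)]
        if not ids:
            raise ValidationError(f"cell type {ct!r} has no samples in the beta matrix")
        cols[ct] = reference_beta.data.loc[probes, ids].mean(axis=1, skipna=True)
    return SignatureMatrix(pd.DataFrame(cols, index=pd.Index(probes, name="probe_id")),
                           metadata)
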