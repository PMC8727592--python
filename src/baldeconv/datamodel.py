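"""Core data containers for methylation deconvolution.

Methylation is represented throughout as *beta values*: per-CpG methylation
fractions in [0, 1], arranged as probes x samples matrices. All cross-matrix
operations align by probe/sample identifier, never by position, so matrices
read from differently-ordered files combine safely.

Proportions are kept on the fraction (0-1) scale internally; the percent
scale appears only at I/O boundaries.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLE_REFERENCE = "reference"
ROLE_MIXTURE = "mixture"

#: Cell types profiled in bronchoalveolar lavage, in conventional order.
DEFAULT_CELL_TYPES = ("AlveolarMacrophage", "Granulocyte", "Lymphocyte", "AEC")


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class AlignmentError(ValueError):
    """Two objects that must share identifiers do not."""


class ParseError(ValueError):
    """A file could not be interpreted as the expected tabular format."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


def _check_unit_interval(data: pd.DataFrame, what: str) -> None:
    arr = data.to_numpy(dtype=float)
    bad = ~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} value {arr[i, j]!r} outside [0, 1] at probe "
            f"{data.index[i]!r}, sample {data.columns[j]!r}"
        )


class _ProbeSampleMatrix:
    """Probes x samples float matrix with unique identifiers on both axes."""

    _value_name = "matrix"

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (probes x samples)")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if validate:
            self.validate()

    def validate(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        _check_unit_interval(self.data, self._value_name)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict_probes(self, probes: Sequence[str]):
        missing = set(probes) - set(self.data.index)
        if missing:
            raise AlignmentError(f"probes absent from matrix: {sorted(missing)[:5]}")
        return type(self)(self.data.loc[list(probes)], validate=False)

    def restrict_samples(self, samples: Sequence[str]):
        missing = set(samples) - set(self.data.columns)
        if missing:
            raise AlignmentError(f"samples absent from matrix: {sorted(missing)[:5]}")
        return type(self)(self.data[list(samples)], validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.shape[0]} probes x {self.shape[1]} samples)"


class BetaMatrix(_ProbeSampleMatrix):
    """Methylation beta values (fractions in [0, 1]); missing values allowed."""

    _value_name = "beta"


class DetectionPMatrix(_ProbeSampleMatrix):
    """Per-probe, per-sample detection p-values in [0, 1].

    Shares the shape/ordering contract of the :class:`BetaMatrix` it
    accompanies; alignment is enforced where the two are consumed together.
    """

    _value_name = "detection p"


SAMPLE_SHEET_COLUMNS = ("sample_id", "role", "cell_type", "pool_size", "batch")


class SampleSheet:
    """Assignment of samples to roles (purified reference vs mixture).

    Reference samples carry a cell-type label and a pool size: the number of
    individuals whose sorted cells were pooled into the hybridised sample.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        df = data.copy()
        for col, default in (("cell_type", None), ("pool_size", 1), ("batch", "")):
            if col not in df.columns:
                df[col] = default
        missing = set(("sample_id", "role")) - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["pool_size"] = df["pool_size"].fillna(1).astype(int)
        df["batch"] = df["batch"].fillna("").astype(str)
        self.data = df.loc[:, list(SAMPLE_SHEET_COLUMNS)].reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        _check_unique(pd.Index(self.data["sample_id"]), "sample ids")
        bad_roles = set(self.data["role"]) - {ROLE_REFERENCE, ROLE_MIXTURE}
        if bad_roles:
            raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
        ref = self.data[self.data["role"] == ROLE_REFERENCE]
        if ref["cell_type"].isna().any() or (ref["cell_type"] == "").any():
            bad = ref.loc[ref["cell_type"].isna() | (ref["cell_type"] == ""), "sample_id"]
            raise ValidationError(f"reference samples without cell type: {list(bad)[:5]}")
        if (self.data["pool_size"] < 1).any():
            raise ValidationError("pool_size must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def reference_ids(self) -> list[str]:
        return list(self.data.loc[self.data["role"] == ROLE_REFERENCE, "sample_id"])

    @property
    def mixture_ids(self) -> list[str]:
        return list(self.data.loc[self.data["role"] == ROLE_MIXTURE, "sample_id"])

    @property
    def cell_types(self) -> list[str]:
        """Cell types of the reference panel, in first-appearance order."""
        ref = self.data[self.data["role"] == ROLE_REFERENCE]
        return list(dict.fromkeys(ref["cell_type"]))

    def samples_of(self, cell_type: str) -> list[str]:
        mask = (self.data["role"] == ROLE_REFERENCE) & (self.data["cell_type"] == cell_type)
        return list(self.data.loc[mask, "sample_id"])

    def cell_type_of(self, sample_id: str) -> str | None:
        row = self.data[self.data["sample_id"] == sample_id]
        if row.empty:
            raise AlignmentError(f"sample {sample_id!r} not in sample sheet")
        ct = row["cell_type"].iloc[0]
        return None if pd.isna(ct) or ct == "" else str(ct)

    def pool_sizes(self) -> pd.Series:
        return self.data.set_index("sample_id")["pool_size"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep, validate=False)

    def __len__(self) -> int:
        return len(self.data)


class ProbeAnnotation:
    """Per-probe exclusion flags (SNP at CpG, sex chromosome, cross-reactive)
    and an optional probe-chemistry stratum label (``design_type``)."""

    FLAGS = ("snp_at_cpg", "on_sex_chromosome", "cross_reactive")

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        df = data.copy()
        if "probe_id" in df.columns:
            df = df.set_index("probe_id")
        df.index = df.index.astype(str)
        for flag in self.FLAGS:
            if flag not in df.columns:
                df[flag] = False
            df[flag] = df[flag].astype(bool)
        if "design_type" not in df.columns:
            df["design_type"] = None
        self.data = df.loc[:, list(self.FLAGS) + ["design_type"]]
        if validate:
            _check_unique(self.data.index, "annotation probe ids")

    @classmethod
    def from_probe_lists(
        cls,
        snp_at_cpg: Iterable[str] = (),
        on_sex_chromosome: Iterable[str] = (),
        cross_reactive: Iterable[str] = (),
    ) -> "ProbeAnnotation":
        probes = sorted(set(snp_at_cpg) | set(on_sex_chromosome) | set(cross_reactive))
        df = pd.DataFrame(index=pd.Index(probes, name="probe_id"))
        df["snp_at_cpg"] = df.index.isin(set(snp_at_cpg))
        df["on_sex_chromosome"] = df.index.isin(set(on_sex_chromosome))
        df["cross_reactive"] = df.index.isin(set(cross_reactive))
        return cls(df)

    def flags_for(self, probe_ids: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
        """Flags reindexed to ``probe_ids``; absent probes get all-False flags.

        Returns the flag frame and the list of probes missing from the
        annotation (the caller decides whether to log them).
        """
        idx = pd.Index([str(p) for p in probe_ids])
        missing = list(idx[~idx.isin(self.data.index)])
        flags = self.data.reindex(idx)
        for flag in self.FLAGS:
            flags[flag] = flags[flag].notna() & flags[flag].eq(True)
        return flags, missing

    def design_types(self, probe_ids: Sequence[str]) -> pd.Series:
        flags, _ = self.flags_for(probe_ids)
        return flags["design_type"]


SCALE_FRACTION = "fraction"
SCALE_PERCENT = "percent"


class ProportionTable:
    """Samples x cell types table of mixture weights.

    Weights are nonnegative; ``scale`` declares whether they are fractions
    (0-1) or percents (0-100). When ``normalized`` is claimed, each row must
    sum to one on the fraction scale.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scale: str = SCALE_FRACTION,
        normalized: bool = False,
        validate: bool = True,
    ):
        if scale not in (SCALE_FRACTION, SCALE_PERCENT):
            raise ValidationError(f"unknown scale {scale!r}")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.scale = scale
        self.normalized = normalized
        if validate:
            self.validate()

    def validate(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "cell types")
        arr = self.data.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative weight at sample {self.data.index[i]!r}, "
                f"cell type {self.data.columns[j]!r}"
            )
        if self.normalized and len(self.data):
            sums = self.as_fraction().data.sum(axis=1)
            off = (sums - 1.0).abs()
            if (off > 1e-6).any():
                bad = sums.index[off > 1e-6][0]
                raise ValidationError(f"row {bad!r} sums to {sums[bad]}, not 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    def as_fraction(self) -> "ProportionTable":
        if self.scale == SCALE_FRACTION:
            return self
        return ProportionTable(
            self.data / 100.0, SCALE_FRACTION, self.normalized, validate=False
        )

    def as_percent(self) -> "ProportionTable":
        if self.scale == SCALE_PERCENT:
            return self
        return ProportionTable(
            self.data * 100.0, SCALE_PERCENT, self.normalized, validate=False
        )


def align_matrices(
    a: _ProbeSampleMatrix, b: _ProbeSampleMatrix
) -> tuple[_ProbeSampleMatrix, _ProbeSampleMatrix]:
    """Require identical probe and sample id sets; reorder ``b`` to ``a``."""
    if set(a.probe_ids) != set(b.probe_ids) or set(a.sample_ids) != set(b.sample_ids):
        raise AlignmentError("matrices do not share probe/sample identifiers")
    reordered = type(b)(b.data.loc[a.probe_ids, a.sample_ids], validate=False)
    return a, reordered
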