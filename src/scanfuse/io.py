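"""Reading, writing and assembly of probe-intensity tables.

The on-disk format is a generic tab-delimited table with a header row
``probe_id  control_type  median_fg`` carrying non-background-subtracted
median foreground fluorescence for one array at one scan level.  Negative
controls may be flagged either by the canonical token ``negative_control``
or by the Agilent spike-in name ``(-)3xSLv1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScanSlice", "ScanSet", "read_intensity_table", "write_intensity_table",
    "assemble_scanset", "FormatError", "AlignmentError",
]

CONTROL_EXPERIMENTAL = "experimental"
CONTROL_NEGATIVE = "negative_control"
CONTROL_OTHER = "other_control"

_NEGATIVE_TOKENS = {CONTROL_NEGATIVE, "(-)3xSLv1", "neg", "-"}
_EXPERIMENTAL_TOKENS = {CONTROL_EXPERIMENTAL, "exp", "0", "false"}

REQUIRED_COLUMNS = ("probe_id", "control_type", "median_fg")


class FormatError(ValueError):
    """A table does not conform to the expected dialect."""


class AlignmentError(ValueError):
    """Slices cannot be assembled into a coherent ScanSet."""


@dataclass
class ScanSlice:
    """One array at one scan level."""

    probe_ids: np.ndarray
    control_type: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        self.control_type = np.asarray(self.control_type)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass
class ScanSet:
    """Raw FLU intensities for a multi-scan study.

    ``intensities`` has shape (probe, array, scan) with the scan axis ordered
    low to high sensitivity (increasing per-array median).
    """

    probe_ids: np.ndarray
    control_type: np.ndarray
    intensities: np.ndarray
    scan_labels: tuple[str, ...]
    ceiling: float = 65535.0
    pmt_settings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        self.control_type = np.asarray(self.control_type)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (probe, array, scan)")
        if self.intensities.shape[0] != self.probe_ids.shape[0]:
            raise ValueError("probe axis does not match probe_ids")
        if self.intensities.min() < 0 or self.intensities.max() > self.ceiling:
            raise ValueError("intensities outside [0, ceiling]")

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_scans(self) -> int:
        return self.intensities.shape[2]

    @property
    def negcontrol_mask(self) -> np.ndarray:
        return self.control_type == CONTROL_NEGATIVE

    def scan(self, j: int) -> np.ndarray:
        """(probe x array) matrix of scan level ``j`` (0 = lowest)."""
        return self.intensities[:, :, j]

    def slice(self, array: int, scan: int) -> ScanSlice:
        return ScanSlice(self.probe_ids, self.control_type,
                         self.intensities[:, array, scan],
                         label=f"array{array}_{self.scan_labels[scan]}")


def _canonical_control(raw: pd.Series) -> np.ndarray:
    tokens = raw.astype(str).str.strip()
    out = np.full(len(tokens), CONTROL_OTHER, dtype=object)
    out[tokens.isin(_EXPERIMENTAL_TOKENS)] = CONTROL_EXPERIMENTAL
    out[tokens.isin(_NEGATIVE_TOKENS)] = CONTROL_NEGATIVE
    return out.astype(str)


def read_intensity_table(path: str | Path, dialect: str = "generic_tsv") -> ScanSlice:
    """Read one array/scan table, preserving row order.

    Raises :class:`FormatError` on a missing column, a non-numeric intensity
    cell (named by row), or a duplicated probe ID.
    """
    if dialect != "generic_tsv":
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    values = pd.to_numeric(df["median_fg"], errors="coerce")
    bad = np.flatnonzero(values.isna().to_numpy())
    if bad.size:
        raise FormatError(
            f"{path.name}: non-numeric intensity {df['median_fg'].iloc[bad[0]]!r} "
            f"at data row {bad[0] + 1}"
        )
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path.name}: duplicate probe ID {dup.iloc[0]!r}")
    return ScanSlice(
        probe_ids=df["probe_id"].to_numpy(),
        control_type=_canonical_control(df["control_type"]),
        values=values.to_numpy(dtype=float),
        label=path.stem,
    )


def write_intensity_table(slc: ScanSlice, path: str | Path) -> None:
    """Write a slice back to the tab-delimited dialect (integer FLU kept exact)."""
    vals = slc.values
    as_int = vals.astype(np.int64)
    col = as_int if np.array_equal(as_int.astype(float), vals) else vals
    pd.DataFrame({
        "probe_id": slc.probe_ids,
        "control_type": slc.control_type,
        "median_fg": col,
    }).to_csv(path, sep="\t", index=False)


def _align(slc: ScanSlice, ref_ids: np.ndarray, ref_label: str) -> ScanSlice:
    if np.array_equal(slc.probe_ids, ref_ids):
        return slc
    ref_set, got_set = set(ref_ids.tolist()), set(slc.probe_ids.tolist())
    if ref_set != got_set:
        only_ref = sorted(ref_set - got_set)[:5]
        only_got = sorted(got_set - ref_set)[:5]
        raise AlignmentError(
            f"probe sets differ between {ref_label!r} and {slc.label!r}: "
            f"missing {only_ref}, unexpected {only_got}"
        )
    order = pd.Index(slc.probe_ids).get_indexer(ref_ids)
    return ScanSlice(ref_ids, slc.control_type[order], slc.values[order],
                     label=slc.label)


def assemble_scanset(
    slices: Sequence[Sequence[ScanSlice]] | Iterable[Iterable[ScanSlice]],
    expected_scans: int | None = None,
    ceiling: float = 65535.0,
) -> ScanSet:
    """Assemble per-array groups of scan slices into one ScanSet.

    ``slices[a]`` holds the scans of array ``a`` in any order; within each
    array the scan axis is ordered by increasing median intensity (PMT
    ranges overlap between arrays, so file naming is not trusted).  Probe
    order follows the first slice; other slices are reordered by ID, and a
    probe-set mismatch raises :class:`AlignmentError`.
    """
    groups = [list(g) for g in slices]
    if not groups or not groups[0]:
        raise AlignmentError("no slices given")
    n_scans = len(groups[0])
    if any(len(g) != n_scans for g in groups):
        raise AlignmentError("arrays have differing numbers of scans")
    if expected_scans is not None and n_scans != expected_scans:
        raise AlignmentError(f"expected {expected_scans} scans, got {n_scans}")

    ref = groups[0][0]
    cube = np.empty((len(ref.probe_ids), len(groups), n_scans))
    for a, group in enumerate(groups):
        aligned = [_align(s, ref.probe_ids, ref.label) for s in group]
        order = np.argsort([s.median for s in aligned], kind="stable")
        for j, k in enumerate(order):
            cube[:, a, j] = aligned[k].values
    return ScanSet(
        probe_ids=ref.probe_ids,
        control_type=ref.control_type,
        intensities=cube,
        scan_labels=tuple(f"scan{j + 1}" for j in range(n_scans)),
        ceiling=ceiling,
    )
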