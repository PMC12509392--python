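"""PSM-level reporter processing: impurity correction, filtering, rollup,
and normalization.

The stages, in the order the pipeline applies them:

1. isotope-impurity correction — each TMT reagent carries a small fraction
   of neighbouring isotopologues, so observed reporter intensities are a
   linear mixture of the true channel signals; correction solves the
   16x16 mixing system per PSM;
2. isolation-interference filter — PSMs whose precursor isolation window
   contained more than 50% foreign ion current are discarded (co-isolation
   compresses reporter ratios);
3. rollup — protein x channel intensities as the sum of corrected reporter
   intensities over the protein's unique-peptide PSMs;
4. group-missingness filter — a protein is dropped when either cohort is
   missing at least half of its values; no imputation is ever applied;
5. log2 transform and per-sample median subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import (
    REPORTER_COLUMNS,
    TMTPRO_CHANNELS,
    ConfigurationError,
    DataError,
    FilterReport,
    ProteinQuantMatrix,
)

_N = len(TMTPRO_CHANNELS)

#: Representative reagent isotope impurity levels (percent of each
#: channel's signal appearing at -2/-1/+1/+2 Da); synthetic values in the
#: range typical of TMTpro certificates of analysis.
_DEFAULT_VENDOR_PERCENTS = {"-2": 0.1, "-1": 0.7, "+1": 3.0, "+2": 0.3}


@dataclass(frozen=True)
class ImpurityMatrix:
    """Channel mixing matrix for reporter-ion isotope impurities.

    Convention: column ``j`` holds the distribution of true channel
    ``j``'s signal across observed channels, so
    ``observed = values @ true``.  Columns sum to at most 1 (signal lost
    outside the 16-channel window is simply absent) and to at least 0.8.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (_N, _N):
            raise DataError(
                f"impurity matrix must be {_N}x{_N}, got {vals.shape}"
            )
        if (vals < 0).any():
            raise DataError("impurity matrix entries must be non-negative")
        colsums = vals.sum(axis=0)
        if (colsums > 1.05).any() or (colsums < 0.8).any():
            raise DataError(
                "impurity matrix column sums outside the [0.8, 1.05] sanity band"
            )
        cond = np.linalg.cond(vals)
        if not np.isfinite(cond) or cond > 1e12:
            raise DataError(
                f"impurity matrix is numerically singular (cond={cond:.3g})"
            )
        object.__setattr__(self, "values", vals)

    @classmethod
    def identity(cls) -> "ImpurityMatrix":
        return cls(np.eye(_N))

    @classmethod
    def from_vendor_table(cls, table: pd.DataFrame) -> "ImpurityMatrix":
        """Convert a vendor-style isotope table into the mixing matrix.

        ``table`` is indexed by channel label with columns ``-2``, ``-1``,
        ``+1``, ``+2`` giving the percentage of each reagent's signal
        observed at the corresponding mass offset.  A 1 Da shift moves the
        signal two positions in the interleaved N/C channel list (e.g.
        126 +1 Da appears in 127C); shifts that fall outside the 16
        channels are lost.
        """
        mat = np.zeros((_N, _N))
        for j, channel in enumerate(TMTPRO_CHANNELS):
            row = table.loc[channel]
            spill = 0.0
            for col, offset in (("-2", -4), ("-1", -2), ("+1", 2), ("+2", 4)):
                pct = float(row.get(col, 0.0))
                spill += pct
                i = j + offset
                if 0 <= i < _N:
                    mat[i, j] = pct / 100.0
            mat[j, j] = (100.0 - spill) / 100.0
        return cls(mat)

    @classmethod
    def default(cls) -> "ImpurityMatrix":
        """Mixing matrix built from representative TMTpro impurity levels."""
        table = pd.DataFrame(
            {k: [v] * _N for k, v in _DEFAULT_VENDOR_PERCENTS.items()},
            index=list(TMTPRO_CHANNELS),
        )
        return cls.from_vendor_table(table)


def _reporter_block(psms: pd.DataFrame) -> list[str]:
    cols = [c for c in REPORTER_COLUMNS if c in psms.columns]
    if len(cols) != _N:
        raise DataError(
            f"PSM table has {len(cols)} reporter columns, expected {_N}"
        )
    return cols


def correct_impurities(
    psms: pd.DataFrame,
    impurity: ImpurityMatrix,
    partial: bool = False,
) -> pd.DataFrame:
    """Undo isotope-impurity mixing on every PSM's reporter vector.

    Solves ``impurity @ x = observed`` per PSM and clips negative
    components of the solution to zero.  By default only fully observed
    PSMs are corrected and PSMs with absent reporters pass through
    unchanged; with ``partial=True`` those PSMs are corrected over the
    observed channel subsystem instead.
    """
    cols = _reporter_block(psms)
    out = psms.copy()
    observed = out[cols].to_numpy(dtype=float)
    present = ~np.isnan(observed)
    full = present.all(axis=1)

    lu = linalg.lu_factor(impurity.values)
    if full.any():
        solved = linalg.lu_solve(lu, observed[full].T).T
        observed[full] = np.clip(solved, 0.0, None)
    if partial:
        for i in np.flatnonzero(~full):
            idx = np.flatnonzero(present[i])
            if idx.size == 0:
                continue
            sub = impurity.values[np.ix_(idx, idx)]
            if np.linalg.cond(sub) > 1e12:
                raise DataError(
                    f"singular impurity subsystem for PSM row {i}"
                )
            observed[i, idx] = np.clip(
                np.linalg.solve(sub, observed[i, idx]), 0.0, None
            )
    out[cols] = observed
    return out


def filter_interference(
    psms: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop PSMs exceeding the isolation-interference threshold.

    A PSM at exactly the threshold is retained ("exceeding" is strict).
    Input order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError("interference threshold must be in [0, 1]")
    interference = psms["interference"].to_numpy(dtype=float)
    if ((interference < 0) | (interference > 1)).any():
        raise DataError("interference fractions must lie in [0, 1]")
    keep = interference <= threshold
    report = FilterReport(
        step="interference_filter",
        n_input=len(psms),
        n_removed=int((~keep).sum()),
    )
    return psms.loc[keep].copy(), report


def rollup_to_protein(
    psms: pd.DataFrame, design: pd.DataFrame
) -> tuple[ProteinQuantMatrix, FilterReport]:
    """Sum corrected PSM reporter intensities to a protein x sample matrix.

    Peptide sequences observed under more than one protein accession
    (shared peptides) are excluded with a warning — razor assignment is
    out of scope.  A protein/sample cell with no contributing intensity
    is missing (NaN); zero totals are coerced to missing, since a zero
    reporter is indistinguishable from not-detected.
    """
    if psms.empty:
        raise DataError("cannot roll up an empty PSM table")
    cols = _reporter_block(psms)

    owners = psms.groupby("sequence")["protein"].nunique()
    shared = set(owners.index[owners > 1])
    if shared:
        warnings.warn(
            f"excluding {len(shared)} shared peptide sequence(s) mapped to "
            "multiple proteins",
            stacklevel=2,
        )
    unique = psms.loc[~psms["sequence"].isin(shared)]
    report = FilterReport(
        step="shared_peptides",
        n_input=len(psms),
        n_removed=len(psms) - len(unique),
        removed=sorted(shared),
    )
    if unique.empty:
        raise DataError("no unique-protein PSMs remain after rollup filtering")

    summed = unique.groupby("protein")[cols].sum(min_count=1)
    summed = summed.mask(summed == 0)

    channel_to_sample = dict(zip(design["channel"], design["sample_id"]))
    sample_cols = []
    for col, channel in zip(cols, TMTPRO_CHANNELS):
        if channel not in channel_to_sample:
            raise DataError(f"design table lacks channel {channel}")
        sample_cols.append(channel_to_sample[channel])
    summed.columns = sample_cols
    summed.index.name = "protein"
    return ProteinQuantMatrix(summed.sort_index(), scale="raw"), report


def filter_missing_by_group(
    matrix: ProteinQuantMatrix,
    design: pd.DataFrame,
    max_missing: float = 0.5,
    inclusive: bool = True,
) -> tuple[ProteinQuantMatrix, FilterReport]:
    """Remove proteins missing too many values within either cohort.

    With the default inclusive rule a protein is removed when the missing
    fraction in the young or the old group is >= ``max_missing`` (a group
    missing exactly half its values counts as removed); no imputation is
    performed on what remains.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ConfigurationError("max_missing must be in [0, 1]")
    missing = matrix.mask
    drop = pd.Series(False, index=matrix.data.index)
    for _, members in design.groupby("group")["sample_id"]:
        cols = [s for s in members if s in missing.columns]
        if not cols:
            raise DataError("design group has no samples in the matrix")
        frac = missing[cols].mean(axis=1)
        drop |= (frac >= max_missing) if inclusive else (frac > max_missing)
    removed = list(matrix.data.index[drop])
    report = FilterReport(
        step="group_missingness_filter",
        n_input=len(matrix.data),
        n_removed=len(removed),
        removed=removed,
    )
    return ProteinQuantMatrix(matrix.data.loc[~drop].copy(), matrix.scale), report


def log2_transform(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Elementwise log2 of a raw matrix; zeros become missing, the mask is
    otherwise unchanged."""
    if matrix.scale != "raw":
        raise ConfigurationError("log2_transform expects a raw-scale matrix")
    vals = matrix.data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals, initial=np.inf) < 0:
            r, c = np.argwhere((vals < 0) & ~np.isnan(vals))[0]
            raise DataError(
                f"negative intensity at protein {matrix.data.index[r]!r}, "
                f"sample {matrix.data.columns[c]!r}"
            )
    vals = np.where(vals == 0, np.nan, vals)
    out = pd.DataFrame(
        np.log2(vals), index=matrix.data.index, columns=matrix.data.columns
    )
    return ProteinQuantMatrix(out, scale="log2")


def median_normalize(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Subtract each sample column's median (over present values).

    After normalization every column's median of present values is zero,
    removing sample-loading differences on the log2 scale.
    """
    if matrix.scale != "log2":
        raise ConfigurationError("median_normalize expects a log2 matrix")
    if matrix.data.isna().all(axis=0).any():
        bad = matrix.data.columns[matrix.data.isna().all(axis=0)]
        raise DataError(f"column(s) with no present values: {list(bad)}")
    out = matrix.data - matrix.data.median(axis=0, skipna=True)
    return ProteinQuantMatrix(out, scale="log2")


def process_psm_table(
    psms: pd.DataFrame,
    impurity: ImpurityMatrix,
    design: pd.DataFrame,
    interference_threshold: float = 0.5,
    max_missing: float = 0.5,
) -> tuple[ProteinQuantMatrix, list[FilterReport]]:
    """Full PSM-to-matrix processing chain.

    Correction -> interference filter -> rollup -> group-missingness
    filter -> log2 -> median normalization.  Returns the normalized log2
    matrix and the per-step filter reports.
    """
    corrected = correct_impurities(psms, impurity)
    filtered, rep_interf = filter_interference(corrected, interference_threshold)
    matrix, rep_shared = rollup_to_protein(filtered, design)
    matrix, rep_missing = filter_missing_by_group(matrix, design, max_missing)
    matrix = median_normalize(log2_transform(matrix))
    return matrix, [rep_interf, rep_shared, rep_missing]
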