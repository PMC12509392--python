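"""Core in-memory containers shared across the pipeline.

The pipeline quantifies a TMTpro 16-plex experiment: sixteen samples, each
labelled with one isobaric channel, measured together in one MS run.  Two
containers travel through every stage: the study design (channel -> sample
mapping with clinical covariates) and the protein-by-sample quantitation
matrix with an explicit missingness convention (NaN = not observed; never
imputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: TMTpro 16-plex reporter channels in nominal mass order.
TMTPRO_CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)

#: Column names used for reporter intensities in PSM tables.
REPORTER_COLUMNS: tuple[str, ...] = tuple(f"reporter_{c}" for c in TMTPRO_CHANNELS)


class DataError(ValueError):
    """A value in the input data violates a pipeline precondition."""


class ConfigurationError(ValueError):
    """A configuration parameter is out of its admissible range."""


def make_study_design(
    n_young: int = 8,
    n_old: int = 8,
    young_female: int = 3,
    old_female: int = 4,
    old_hypertensive: int = 4,
) -> pd.DataFrame:
    """Build a channel -> sample design table for a two-cohort 16-plex run.

    Defaults mirror a young (n=8) vs old (n=8) nephrectomy cohort: 3/8
    young and 4/8 old samples female, hypertension present only in the old
    group (4/8).  Young samples occupy the low-mass channels.

    Returns a DataFrame with columns ``channel``, ``sample_id``, ``group``
    (young/old), ``sex`` (female/male), ``hypertension`` (bool).
    """
    n = n_young + n_old
    if n > len(TMTPRO_CHANNELS):
        raise ConfigurationError(
            f"{n} samples exceed the {len(TMTPRO_CHANNELS)} TMTpro channels"
        )
    rows = []
    for i in range(n_young):
        rows.append(
            {
                "channel": TMTPRO_CHANNELS[i],
                "sample_id": f"Y{i + 1}",
                "group": "young",
                "sex": "female" if i < young_female else "male",
                "hypertension": False,
            }
        )
    for i in range(n_old):
        rows.append(
            {
                "channel": TMTPRO_CHANNELS[n_young + i],
                "sample_id": f"O{i + 1}",
                "group": "old",
                "sex": "female" if i < old_female else "male",
                "hypertension": i < old_hypertensive,
            }
        )
    design = pd.DataFrame(rows)
    validate_study_design(design)
    return design


def validate_study_design(design: pd.DataFrame) -> None:
    required = {"channel", "sample_id", "group", "sex", "hypertension"}
    missing = required - set(design.columns)
    if missing:
        raise DataError(f"design table missing columns: {sorted(missing)}")
    if design["channel"].duplicated().any():
        raise DataError("design table has duplicated channels")
    if design["sample_id"].duplicated().any():
        raise DataError("design table has duplicated sample ids")
    bad = set(design["channel"]) - set(TMTPRO_CHANNELS)
    if bad:
        raise DataError(f"unknown TMTpro channels in design: {sorted(bad)}")
    bad_group = set(design["group"]) - {"young", "old"}
    if bad_group:
        raise DataError(f"group must be young/old, got {sorted(bad_group)}")
    if design[["group", "sex", "hypertension"]].isna().any().any():
        raise DataError("covariates must be non-missing")


@dataclass
class ProteinQuantMatrix:
    """Protein x sample quantitation matrix.

    ``data`` is indexed by protein accession with sample-id columns; NaN
    marks a missing (unquantified) cell.  ``scale`` records whether values
    are raw summed reporter intensities or log2-transformed.
    """

    data: pd.DataFrame
    scale: str = "raw"  # {"raw", "log2"}

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ConfigurationError(f"unknown scale tag {self.scale!r}")
        if self.scale == "raw":
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise DataError("raw intensities must be non-negative")

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True where the value is undefined)."""
        return self.data.isna()

    def copy(self) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(self.data.copy(), self.scale)


@dataclass
class FilterReport:
    """Bookkeeping for a filtering step: what was removed and why."""

    step: str
    n_input: int
    n_removed: int
    removed: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed
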