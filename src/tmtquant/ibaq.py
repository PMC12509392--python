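"""iBAQ protein abundance from peptide intensities and an in-silico digest.

iBAQ (intensity-based absolute quantification) estimates a protein's molar
abundance as the sum of its quantified peptide intensities divided by the
number of theoretically observable tryptic peptides.  The theoretical count
comes from an in-silico trypsin digest (cleavage C-terminal to K/R, blocked
by a following proline) restricted to the mass-spectrometry-observable
length window, 6-30 residues by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .containers import REPORTER_COLUMNS, ConfigurationError, DataError

_STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Trypsin: cleave after K or R unless the next residue is proline.  A
#: C-terminal K/R is not a site (the cut would only split off an empty
#: fragment, duplicating missed-cleavage variants).
TRYPSIN_RULE = r"[KR](?!P|$)"


@dataclass(frozen=True)
class DigestRule:
    """Parameters of the in-silico tryptic digest.

    ``missed_cleavages`` applies to the generated peptide list; the
    theoretical-peptide count conventionally uses 0 (fully cleaved).
    ``min_len``/``max_len`` bound the observable window (inclusive).
    """

    missed_cleavages: int = 0
    min_len: int = 6
    max_len: int = 30

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ConfigurationError("missed_cleavages must be >= 0")
        if self.min_len > self.max_len or self.min_len < 1:
            raise ConfigurationError(
                f"invalid length window {self.min_len}-{self.max_len}"
            )


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise DataError("empty protein sequence")
    bad = set(sequence) - _STANDARD_RESIDUES
    if bad:
        raise DataError(f"non-standard residues in sequence: {sorted(bad)}")


def digest_in_silico(sequence: str, rule: DigestRule = DigestRule()) -> list[str]:
    """All tryptic peptides of ``sequence`` in N- to C-terminal order.

    Peptides are returned unfiltered by length, duplicates included, with
    missed-cleavage variants appended per cleavage window.
    """
    _check_sequence(sequence)
    return [
        pep
        for _, pep in _pyt_parser.icleave(
            sequence, TRYPSIN_RULE, missed_cleavages=rule.missed_cleavages
        )
    ]


def count_theoretical_peptides(
    sequence: str, rule: DigestRule = DigestRule()
) -> int:
    """Number of distinct digest peptides inside the observable window."""
    peptides = digest_in_silico(sequence, rule)
    return len(
        {p for p in peptides if rule.min_len <= len(p) <= rule.max_len}
    )


@dataclass(frozen=True)
class IbaqRecord:
    protein: str
    summed_intensity: float
    n_theoretical: int
    ibaq: float = field(init=False)
    ibaq_log10: float = field(init=False)

    def __post_init__(self) -> None:
        if self.summed_intensity < 0:
            raise DataError(f"negative summed intensity for {self.protein}")
        if self.n_theoretical > 0 and self.summed_intensity > 0:
            ibaq = self.summed_intensity / self.n_theoretical
            log10 = math.log10(ibaq)
        else:
            ibaq, log10 = math.nan, math.nan
        object.__setattr__(self, "ibaq", ibaq)
        object.__setattr__(self, "ibaq_log10", log10)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ibaq)


def compute_ibaq(
    protein: str, summed_intensity: float, n_theoretical: int
) -> IbaqRecord:
    """One protein's iBAQ; undefined (NaN) when the denominator or the
    numerator is zero."""
    return IbaqRecord(protein, summed_intensity, n_theoretical)


def ibaq_table(
    psms: pd.DataFrame,
    proteins: dict[str, str],
    rule: DigestRule = DigestRule(),
) -> pd.DataFrame:
    """Per-protein iBAQ from a (corrected, pre-normalization) PSM table.

    The numerator is each protein's total reporter intensity summed over
    all its PSMs and all channels — iBAQ describes overall abundance in
    the experiment, not a per-channel quantity.  ``proteins`` maps
    accession to sequence (the FASTA content).

    Returns a DataFrame with columns ``protein``, ``summed_intensity``,
    ``n_theoretical``, ``ibaq_log10``.
    """
    reporter_cols = [c for c in REPORTER_COLUMNS if c in psms.columns]
    summed = (
        psms.groupby("protein")[reporter_cols]
        .sum(min_count=1)
        .sum(axis=1, skipna=True)
    )
    rows = []
    for accession, intensity in summed.items():
        if accession not in proteins:
            raise DataError(f"protein {accession} absent from sequence database")
        count_rule = DigestRule(0, rule.min_len, rule.max_len)
        rec = compute_ibaq(
            str(accession),
            float(intensity) if np.isfinite(intensity) else 0.0,
            count_theoretical_peptides(proteins[accession], count_rule),
        )
        rows.append(
            {
                "protein": rec.protein,
                "summed_intensity": rec.summed_intensity,
                "n_theoretical": rec.n_theoretical,
                "ibaq_log10": rec.ibaq_log10,
            }
        )
    return pd.DataFrame(rows)


def ibaq_rank_table(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Rank proteins by descending log10 iBAQ for abundance-rank plots.

    Undefined iBAQ values are excluded.  Ties keep a stable order by
    accession.  Returns the ranked table (with a 1-based ``rank`` column)
    and the median log10 iBAQ over defined records.
    """
    defined = records.dropna(subset=["ibaq_log10"])
    if defined.empty:
        raise DataError("no defined iBAQ records to rank")
    ranked = defined.sort_values(
        ["ibaq_log10", "protein"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    median = float(ranked["ibaq_log10"].median())
    return ranked, median
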