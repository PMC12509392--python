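"""Readers and writers for the pipeline's tab-separated interchange files.

All tables are TSV with a header row; missing reporter intensities are
empty fields.  Protein databases are standard FASTA (60-character wrap,
via Biopython).  PSM tables follow a MaxQuant-evidence-like layout with a
configurable column-name map so real evidence exports can be adapted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    REPORTER_COLUMNS,
    TMTPRO_CHANNELS,
    DataError,
    ProteinQuantMatrix,
    validate_study_design,
)
from .quant import ImpurityMatrix

PSM_COLUMNS = ("sequence", "protein", "interference", *REPORTER_COLUMNS)


def write_fasta(db: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in db.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    db = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not db:
        raise DataError(f"no FASTA records in {path}")
    return db


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False, na_rep="")


def read_psm_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a PSM TSV; ``column_map`` renames dialect columns (e.g. a
    MaxQuant evidence export) onto the pipeline's names.  Zero reporter
    intensities are coerced to missing."""
    psms = pd.read_csv(path, sep="\t")
    if column_map:
        psms = psms.rename(columns=column_map)
    missing = set(PSM_COLUMNS) - set(psms.columns)
    if missing:
        raise DataError(f"PSM table missing columns: {sorted(missing)}")
    psms = psms.loc[:, list(PSM_COLUMNS)]
    block = psms[list(REPORTER_COLUMNS)].astype(float)
    psms[list(REPORTER_COLUMNS)] = block.mask(block == 0)
    return psms


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    if "hypertension" in design.columns:
        design["hypertension"] = design["hypertension"].astype(bool)
    validate_study_design(design)
    return design


def write_impurity(impurity: ImpurityMatrix, path: str | Path) -> None:
    pd.DataFrame(
        impurity.values, index=list(TMTPRO_CHANNELS), columns=list(TMTPRO_CHANNELS)
    ).to_csv(path, sep="\t")


def read_impurity(path: str | Path, vendor: bool = False) -> ImpurityMatrix:
    """Read an impurity TSV: either the full 16x16 mixing matrix (channels
    as row/column labels) or, with ``vendor=True``, a vendor-style table
    of -2/-1/+1/+2 isotope percentages per channel."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if vendor:
        return ImpurityMatrix.from_vendor_table(table)
    return ImpurityMatrix(table.loc[list(TMTPRO_CHANNELS), list(TMTPRO_CHANNELS)].to_numpy())


def write_matrix(matrix: ProteinQuantMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="")


def read_matrix(path: str | Path, scale: str = "log2") -> ProteinQuantMatrix:
    data = pd.read_csv(path, sep="\t", index_col=0)
    return ProteinQuantMatrix(data.astype(float), scale=scale)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_config_file(path: str | Path) -> dict[str, str]:
    """Parse a key = value text config (one pair per line, # comments)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DataError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    if "," in value:
        parts = [p.strip() for p in value.split(",")]
        return tuple(_coerce(p) for p in parts)
    return value


def config_from_file(path: str | Path, seed: int | None = None):
    """Build a :class:`~tmtquant.simulate.SimulationConfig` from a
    key-value config file, optionally overriding the seed."""
    from .simulate import SimulationConfig

    raw = {k: _coerce(v) for k, v in read_config_file(path).items()}
    if seed is not None:
        raw["seed"] = seed
    unknown = set(raw) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def write_filter_reports(reports: list, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "step": r.step,
                "n_input": r.n_input,
                "n_removed": r.n_removed,
                "n_kept": r.n_kept,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)


def write_de_results(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_de_results(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t")
    de["significant"] = de["significant"].astype(bool)
    return de


def write_json(obj: dict, path: str | Path) -> None:
    import json

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
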