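"""Table and JSON input/output.

All tables are delimited text (TSV by default, CSV accepted) with exact,
case-sensitive headers; metadata travels in leading comment lines of the
form ``#key=value``.  Headers are strict on purpose: silent unit
mistakes are the dominant failure mode in force-spectroscopy data
exchange, so a file with a wrong or re-cased column name is rejected
with the expected header in the message.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .afm_stats import ContourTrace
from .equilibrium_binding import DeltaLCurve
from .errors import FormatError
from .fec_model import ForceExtensionCurve
from .perturbation_kinetics import KineticTrace

FEC_COLUMNS = ["extension_um", "force_pN"]
TRACE_COLUMNS = ["time_s", "force_pN", "length_um", "phase"]
DELTA_L_COLUMNS = ["force_pN", "delta_L_um"]
CONTOUR_COLUMNS = ["x_nm", "y_nm"]  # optional third: height_nm

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path, dialect: Optional[str]) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in _SEPS:
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    return _SEPS[dialect]


def _split_metadata(text: str):
    meta, body = {}, []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
        else:
            body.append(line)
    return meta, "\n".join(body)


def _read_table(path, sep, expected, optional=()):
    text = Path(path).read_text()
    meta, body = _split_metadata(text)
    df = pd.read_csv(_io.StringIO(body), sep=sep, dtype=str,
                     skip_blank_lines=True)
    cols = list(df.columns)
    for name in expected:
        if name not in cols:
            raise FormatError(
                f"{path}: missing column {name!r}; expected header "
                f"{list(expected)} (case-sensitive)"
            )
    extra = [c for c in cols if c not in expected and c not in optional]
    if extra:
        raise FormatError(f"{path}: unexpected columns {extra}")
    numeric = {}
    for name in cols:
        if name == "phase":
            numeric[name] = df[name].to_numpy()
            continue
        try:
            numeric[name] = df[name].astype(float).to_numpy()
        except (TypeError, ValueError):
            col = df[name]
            for i, cell in enumerate(col):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} in column "
                        f"{name!r}, data row {i + 1}"
                    ) from None
            raise
    return meta, numeric


def read_fec(path, dialect: Optional[str] = None) -> ForceExtensionCurve:
    """Read one force-extension curve from a TSV/CSV table."""
    sep = _sep_for(path, dialect)
    meta, cols = _read_table(path, sep, FEC_COLUMNS)
    return ForceExtensionCurve(
        extension=cols["extension_um"],
        force=cols["force_pN"],
        tmpyp=float(meta.get("tmpyp_nM", 0.0)),
        nacl=float(meta.get("nacl_M", 0.0)),
        pulling_rate=float(meta.get("pulling_rate_um_s", 0.0)),
        direction=meta.get("direction", "stretch"),
        label=meta.get("label", ""),
    )


def write_fec(fec: ForceExtensionCurve, path, dialect: Optional[str] = None):
    sep = _sep_for(path, dialect)
    lines = [
        f"#tmpyp_nM={fec.tmpyp:g}",
        f"#nacl_M={fec.nacl:g}",
        f"#pulling_rate_um_s={fec.pulling_rate:g}",
        f"#direction={fec.direction}",
    ]
    if fec.label:
        lines.append(f"#label={fec.label}")
    lines.append(sep.join(FEC_COLUMNS))
    for x, f in zip(fec.extension, fec.force):
        lines.append(f"{x:.9g}{sep}{f:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_kinetic_trace(path, dialect: Optional[str] = None) -> KineticTrace:
    sep = _sep_for(path, dialect)
    meta, cols = _read_table(path, sep, TRACE_COLUMNS)
    return KineticTrace(
        time=cols["time_s"],
        force=cols["force_pN"],
        length=cols["length_um"],
        phase=cols["phase"],
        tmpyp=float(meta.get("tmpyp_nM", 0.0)),
        protocol=meta.get("protocol", "force_jump"),
    )


def write_kinetic_trace(tr: KineticTrace, path, dialect: Optional[str] = None):
    sep = _sep_for(path, dialect)
    lines = [f"#tmpyp_nM={tr.tmpyp:g}", f"#protocol={tr.protocol}",
             sep.join(TRACE_COLUMNS)]
    phase = tr.phase if tr.phase is not None else np.full(tr.time.size, "na")
    for t, f, L, ph in zip(tr.time, tr.force, tr.length, phase):
        lines.append(f"{t:.9g}{sep}{f:.9g}{sep}{L:.9g}{sep}{ph}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_delta_l(path, dialect: Optional[str] = None) -> DeltaLCurve:
    sep = _sep_for(path, dialect)
    meta, cols = _read_table(path, sep, DELTA_L_COLUMNS)
    return DeltaLCurve(
        force=cols["force_pN"],
        delta_l=cols["delta_L_um"],
        tmpyp=float(meta.get("tmpyp_nM", 0.0)),
        nacl=float(meta.get("nacl_M", 0.0)),
    )


def write_delta_l(dl: DeltaLCurve, path, dialect: Optional[str] = None):
    sep = _sep_for(path, dialect)
    lines = [f"#tmpyp_nM={dl.tmpyp:g}", f"#nacl_M={dl.nacl:g}",
             sep.join(DELTA_L_COLUMNS)]
    for f, d in zip(dl.force, dl.delta_l):
        lines.append(f"{f:.9g}{sep}{d:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contour_trace(path, dialect: Optional[str] = None) -> ContourTrace:
    sep = _sep_for(path, dialect)
    _, cols = _read_table(path, sep, CONTOUR_COLUMNS, optional=("height_nm",))
    height = cols.get("height_nm")
    return ContourTrace(
        path=np.column_stack([cols["x_nm"], cols["y_nm"]]),
        height=height,
    )


def write_stiffness_table(sc, path, dialect: Optional[str] = None):
    sep = _sep_for(path, dialect)
    lines = [sep.join(["extension_um", "stiffness_pN_per_um"])]
    for x, k in zip(sc.extension, sc.df_dx):
        lines.append(f"{x:.9g}{sep}{k:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj: dict, path):
    """Deterministic JSON dump: sorted keys, fixed float formatting."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")
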