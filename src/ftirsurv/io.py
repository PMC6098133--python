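"""Reading, validation and canonicalisation of spectra and cohort tables.

A :class:`Spectrum` is a sampled absorbance curve on a strictly increasing
wavenumber grid (cm^-1) together with sample metadata: which patient it came
from, which tissue it measures and which replicate it is.  Three tissue types
are recognised:

``t_b``
    tumour sampled at diagnostic biopsy, before neoadjuvant chemotherapy;
``t_t``
    tumour resected after completion of neoadjuvant chemotherapy;
``t_n``
    normal bone tissue from outside the tumour area.

Spectrum files may arrive as two-column text (comma or whitespace delimited,
optional single header line) or as JCAMP-DX with an AFFN-encoded
``XYDATA=(X++(Y..Y))`` or ``XYPOINTS`` table.  Vendor exports commonly store
wavenumbers in descending order; spectra are canonicalised to ascending order
on read so one convention holds everywhere downstream.
"""

from __future__ import annotations

import csv as _csv
import io as _stdio
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUE_TYPES = ("t_b", "t_t", "t_n")

__all__ = [
    "TISSUE_TYPES",
    "Spectrum",
    "CohortManifest",
    "PatientRecord",
    "SpectrumParseError",
    "read_spectrum",
    "write_csv",
    "load_cohort",
    "resample_to_grid",
]


class SpectrumParseError(ValueError):
    """A spectrum stream could not be parsed in its declared format."""


def _canonical_tissue(value: str) -> str:
    t = str(value).strip().lower()
    if t not in TISSUE_TYPES:
        raise ValueError(
            f"unknown tissue type {value!r}; expected one of {TISSUE_TYPES}"
        )
    return t


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    patient_id: str = ""
    tissue_type: str = "t_b"
    replicate_index: int = 1
    source_path: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise ValueError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances"
            )
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.isfinite(wn).all() and np.isfinite(ab).all()):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(wn) <= 0):
            if np.unique(wn).size < wn.size:
                raise ValueError("duplicate wavenumbers in spectrum")
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "tissue_type", _canonical_tissue(self.tissue_type))
        if int(self.replicate_index) < 1:
            raise ValueError("replicate_index must be a positive integer")
        object.__setattr__(self, "replicate_index", int(self.replicate_index))

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_absorbance(self, values: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy of this spectrum with new absorbance values on the same grid."""
        return replace(self, absorbance=np.asarray(values, dtype=float), **meta_updates)


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and survival outcomes for one patient.

    Times are in months; ``pfs_event``/``os_event`` are 1 for an observed
    event (progression/relapse resp. death) and 0 for right censoring.
    Any field may be None when the source table leaves the cell empty.
    """

    patient_id: str
    gender: str | None = None
    age_years: float | None = None
    disease_extent: str | None = None
    site: str | None = None
    necrosis_pct: float | None = None
    radiotherapy: int | None = None
    auto_hsct: int | None = None
    adjuvant_ctx: str | None = None
    pfs_months: float | None = None
    pfs_event: int | None = None
    os_months: float | None = None
    os_event: int | None = None


@dataclass
class CohortManifest:
    """Rows linking (patient_id, tissue_type, replicate_index) to spectrum files."""

    rows: pd.DataFrame  # columns: patient_id, tissue_type, replicate, path

    def __post_init__(self) -> None:
        required = {"patient_id", "tissue_type", "replicate", "path"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        self.rows = self.rows.copy()
        self.rows["patient_id"] = self.rows["patient_id"].astype(str)
        self.rows["tissue_type"] = self.rows["tissue_type"].map(_canonical_tissue)
        self.rows["replicate"] = self.rows["replicate"].astype(int)
        key = self.rows[["patient_id", "tissue_type", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate manifest key "
                f"({dup['patient_id']}, {dup['tissue_type']}, {dup['replicate']})"
            )

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# spectrum readers


def _parse_two_column_text(text: str) -> tuple[np.ndarray, np.ndarray]:
    wn, ab = [], []
    lines = text.splitlines()
    start = 0
    # auto-detect a single header line by a non-numeric first token
    for i, line in enumerate(lines):
        if line.strip() and not line.lstrip().startswith("#"):
            token = line.replace(",", " ").split()[0]
            try:
                float(token)
            except ValueError:
                start = i + 1
            break
    for lineno, line in enumerate(lines[start:], start=start + 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) < 2:
            raise SpectrumParseError(f"line {lineno}: expected two columns, got {stripped!r}")
        try:
            wn.append(float(parts[0]))
            ab.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"line {lineno}: non-numeric value in {stripped!r}") from exc
    return np.array(wn), np.array(ab)


_JCAMP_COMPRESSED = "SQZ/DIF/DUP"
# AFFN data are plain decimal numbers; these lead characters mark compressed forms
_SQZ_DIGITS = set("@ABCDEFGHIabcdefghi")
_DIF_DIGITS = set("%JKLMNOPQRjklmnopqrSTUVWXYZs")


def _parse_jcamp(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse the AFFN XYDATA=(X++(Y..Y)) / XYPOINTS subset of JCAMP-DX."""
    lines = text.splitlines()
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # "xydata" | "xypoints"
    for raw in lines:
        line = raw.split("$$")[0].rstrip()  # strip JCAMP comments
        if line.startswith("##"):
            if mode and data_lines:
                break  # a new label ends the data table
            name, _, value = line[2:].partition("=")
            name = name.strip().upper().replace(" ", "")
            value = value.strip()
            labels[name] = value
            if name == "XYDATA":
                if "X++" not in value.replace(" ", ""):
                    raise SpectrumParseError(f"unsupported XYDATA form {value!r}")
                mode = "xydata"
            elif name == "XYPOINTS":
                mode = "xypoints"
        elif mode and line.strip():
            data_lines.append(line.strip())
    if mode is None:
        raise SpectrumParseError("no XYDATA or XYPOINTS table found in JCAMP-DX stream")

    xfactor = float(labels.get("XFACTOR", 1.0))
    yfactor = float(labels.get("YFACTOR", 1.0))

    if mode == "xypoints":
        pairs_text = " ".join(data_lines).replace(";", " ").replace(",", " ")
        values = [float(tok) for tok in pairs_text.split()]
        if len(values) % 2:
            raise SpectrumParseError("odd token count in XYPOINTS table")
        arr = np.array(values).reshape(-1, 2)
        return arr[:, 0] * xfactor, arr[:, 1] * yfactor

    wn: list[float] = []
    ab: list[float] = []
    for lineno, line in enumerate(data_lines, start=1):
        for ch in line:
            if ch in _SQZ_DIGITS or ch in _DIF_DIGITS:
                raise SpectrumParseError(
                    f"compressed ({_JCAMP_COMPRESSED}) JCAMP-DX encoding is not "
                    "supported; export the file in AFFN (plain numeric) form"
                )
        tokens = line.replace(",", " ").split()
        if len(tokens) < 2:
            raise SpectrumParseError(f"XYDATA line {lineno}: expected X then Y values")
        try:
            x0 = float(tokens[0])
            ys = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise SpectrumParseError(f"XYDATA line {lineno}: non-numeric token") from exc
        if "DELTAX" in labels:
            dx = float(labels["DELTAX"])
        else:
            first = float(labels["FIRSTX"])
            last = float(labels["LASTX"])
            npts = int(float(labels["NPOINTS"]))
            dx = (last - first) / (npts - 1) if npts > 1 else 0.0
        for j, y in enumerate(ys):
            wn.append((x0 + j * dx / xfactor) * xfactor)
            ab.append(y * yfactor)
    return np.array(wn), np.array(ab)


def read_spectrum(
    source: str | Path | IO[str],
    format: str = "csv",
    *,
    patient_id: str = "",
    tissue_type: str = "t_b",
    replicate_index: int = 1,
) -> Spectrum:
    """Read one spectrum from a file path or text stream.

    Parameters
    ----------
    source
        Path or open text stream.
    format
        ``"csv"`` (two-column text, comma or whitespace delimited, optional
        header) or ``"jcamp-dx"`` (AFFN XYDATA/XYPOINTS subset).

    The returned spectrum is always sorted by ascending wavenumber regardless
    of file order; duplicate wavenumbers are rejected.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        src_path = str(source)
    else:
        text = source.read()
        src_path = getattr(source, "name", None)

    fmt = format.lower().replace("_", "-")
    if fmt == "csv":
        wn, ab = _parse_two_column_text(text)
    elif fmt in ("jcamp-dx", "jcamp", "jdx", "dx"):
        wn, ab = _parse_jcamp(text)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")

    if wn.size < 2:
        raise SpectrumParseError(f"degenerate spectrum: {wn.size} data point(s), need >= 2")
    if np.unique(wn).size < wn.size:
        dup = wn[pd.Index(wn).duplicated()][0]
        raise SpectrumParseError(f"duplicate wavenumber {dup} in spectrum")
    order = np.argsort(wn)
    return Spectrum(
        wavenumbers=wn[order],
        absorbance=ab[order],
        patient_id=patient_id,
        tissue_type=tissue_type,
        replicate_index=replicate_index,
        source_path=src_path,
    )


def write_csv(spectrum: Spectrum, target: str | Path | IO[str]) -> None:
    """Write a spectrum as two-column CSV with header, 12 significant digits."""
    buf = _stdio.StringIO()
    writer = _csv.writer(buf, lineterminator="\n")
    writer.writerow(["wavenumber_cm-1", "absorbance"])
    for x, y in zip(spectrum.wavenumbers, spectrum.absorbance):
        writer.writerow([f"{x:.12g}", f"{y:.12g}"])
    text = buf.getvalue()
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


# ---------------------------------------------------------------------------
# cohort loading


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(f)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


def read_clinical_table(clinical_path: str | Path) -> list[PatientRecord]:
    """Read the clinical CSV (empty cells meaning missing) into records."""
    df = pd.read_csv(clinical_path, dtype={"patient_id": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                gender=_opt_str(row.get("gender")),
                age_years=_opt_float(row.get("age_years")),
                disease_extent=_opt_str(row.get("disease_extent")),
                site=_opt_str(row.get("site")),
                necrosis_pct=_opt_float(row.get("necrosis_pct")),
                radiotherapy=_opt_int(row.get("radiotherapy")),
                auto_hsct=_opt_int(row.get("auto_hsct")),
                adjuvant_ctx=_opt_str(row.get("adjuvant_ctx")),
                pfs_months=_opt_float(row.get("pfs_months")),
                pfs_event=_opt_int(row.get("pfs_event")),
                os_months=_opt_float(row.get("os_months")),
                os_event=_opt_int(row.get("os_event")),
            )
        )
    return records


def load_cohort(
    manifest_path: str | Path, clinical_path: str | Path
) -> tuple[CohortManifest, list[PatientRecord], list[Spectrum]]:
    """Load a cohort: manifest rows, clinical records and all spectra.

    Patients present in the clinical table but lacking normal-bone (``t_n``)
    spectra are loaded normally — missing normal tissue is expected, not an
    error.  Replicate counts per (patient, tissue) are logged.
    """
    manifest_path = Path(manifest_path)
    manifest = CohortManifest(pd.read_csv(manifest_path, dtype={"patient_id": str}))
    records = read_clinical_table(clinical_path)
    clinical_ids = {r.patient_id for r in records}

    manifest_ids = set(manifest.rows["patient_id"])
    orphans = manifest_ids - clinical_ids
    if orphans:
        raise ValueError(
            f"manifest patients missing from clinical table: {sorted(orphans)}"
        )
    if len(manifest) == 0:
        logger.warning("empty manifest: cohort has no spectra")

    spectra: list[Spectrum] = []
    for _, row in manifest.rows.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise FileNotFoundError(
                f"spectrum file not found for patient {row['patient_id']} "
                f"tissue {row['tissue_type']} replicate {row['replicate']}: {path}"
            )
        spectra.append(
            read_spectrum(
                path,
                format="jcamp-dx" if path.suffix.lower() in (".jdx", ".dx") else "csv",
                patient_id=row["patient_id"],
                tissue_type=row["tissue_type"],
                replicate_index=row["replicate"],
            )
        )

    counts = manifest.rows.groupby(["patient_id", "tissue_type"]).size()
    for (pid, tissue), n in counts.items():
        logger.info("patient %s tissue %s: %d replicate(s)", pid, tissue, n)
    no_tn = sorted(
        pid
        for pid in clinical_ids
        if pid not in set(
            manifest.rows.loc[manifest.rows["tissue_type"] == "t_n", "patient_id"]
        )
    )
    if no_tn:
        logger.info("%d patient(s) without t_n spectra: %s", len(no_tn), no_tn)
    return manifest, records, spectra


def resample_to_grid(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavenumber grid.

    The grid must lie within the closed support of ``s``; extrapolation is an
    error.  Exact at grid points shared with the input.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] extends outside the spectrum "
            f"support [{lo}, {hi}]; extrapolation is not supported"
        )
    values = np.interp(grid, s.wavenumbers, s.absorbance)
    return replace(s, wavenumbers=grid, absorbance=values)
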