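"""Plate ingestion, fraction-affected normalization, and assay QC.

A screen is a collection of barcoded 384-well plates.  Each well carries a
role (vehicle ``DMSO``, positive control ``POSCON``, ``DRUG`` at a dose, or
``EMPTY``) and a raw luminescence value (RLU).  Drug wells are normalized
to fraction affected::

    FA = 1 - (X_c / X_DMSO)

where ``X_DMSO`` is the *median* RLU of on-plate vehicle wells.  FA is not
clipped here; clipping to [0, 1] happens only when integrating fitted
curves, so growth-stimulation signals (FA < 0) stay inspectable.

QC statistics:

* ``z_prime`` -- 1 - 3 (sd_pos + sd_veh) / |mean_pos - mean_veh| on raw RLU.
* ``msr`` -- minimum significance ratio, 10 ** (2 * sqrt(2) * s) with s the
  standard deviation of replicate log10 potencies.
* ``ddct_human_content`` -- fraction of human DNA from qPCR Ct values by
  the 2^(-ddCt) relative-quantification rule.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import (DegeneratePlateError, InsufficientDataError,
                     PdxScreenError, PlateFormatError, QCFatalError)

__all__ = [
    "Plate", "ROLES", "read_plates", "write_plates", "model_from_barcode",
    "normalize", "normalize_screen", "z_prime", "msr",
    "ddct_human_content", "qc_report", "replicate_potencies",
]

ROLES = ("DMSO", "POSCON", "DRUG", "EMPTY")

PLATE_COLUMNS = ["plate_barcode", "well", "role", "drug_id",
                 "dose_uM", "replicate", "rlu"]

_WELL_RE = re.compile(r"^([A-P])(0[1-9]|1[0-9]|2[0-4])$")


@dataclass
class Plate:
    """One barcoded 384-well plate."""

    barcode: str
    wells: pd.DataFrame  # columns: well, role, drug_id, dose_uM, replicate, rlu

    def __post_init__(self):
        if self.wells["well"].duplicated().any():
            dupes = self.wells.loc[self.wells["well"].duplicated(), "well"]
            raise PlateFormatError(
                f"plate {self.barcode}: duplicate wells {sorted(set(dupes))}")
        if not (self.wells["role"] == "DMSO").any():
            raise QCFatalError(
                f"plate {self.barcode}: no DMSO wells, cannot normalize")

    def rlu(self, role: str) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == role, "rlu"].to_numpy(float)


def model_from_barcode(barcode: str) -> str:
    """Model id encoded in a plate barcode (``<model>-<nn>``)."""
    return barcode.rsplit("-", 1)[0]


def _validate_rows(df: pd.DataFrame) -> None:
    problems: List[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        well = str(row["well"])
        if not _WELL_RE.match(well):
            problems.append(f"line {line}: bad well id {well!r}")
        if row["role"] not in ROLES:
            problems.append(f"line {line}: unknown role {row['role']!r}")
        rlu = row["rlu"]
        if not np.isfinite(rlu) or rlu < 0:
            problems.append(f"line {line}: negative or non-finite rlu {rlu!r}")
    if problems:
        raise PlateFormatError("; ".join(problems))


def read_plates(path) -> List[Plate]:
    """Read a plate CSV into typed :class:`Plate` objects.

    Raises :class:`PlateFormatError` for malformed rows (with line
    numbers) and :class:`QCFatalError` for plates without DMSO wells.
    """
    df = pd.read_csv(path, dtype={"plate_barcode": str, "well": str,
                                  "role": str, "drug_id": str})
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise PlateFormatError(f"missing columns: {sorted(missing)}")
    _validate_rows(df)
    plates = []
    for barcode, grp in df.groupby("plate_barcode", sort=True):
        plates.append(Plate(barcode=str(barcode),
                            wells=grp.drop(columns="plate_barcode")
                                     .reset_index(drop=True)))
    return plates


def write_plates(plates: Iterable[Plate], path) -> None:
    frames = []
    for plate in plates:
        w = plate.wells.copy()
        w.insert(0, "plate_barcode", plate.barcode)
        frames.append(w)
    pd.concat(frames, ignore_index=True)[PLATE_COLUMNS].to_csv(path,
                                                               index=False)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(plate: Plate) -> pd.DataFrame:
    """Fraction affected for every drug well of one plate.

    Returns a frame with columns drug_id, dose_uM, replicate, FA.
    """
    dmso = plate.rlu("DMSO")
    x_dmso = float(np.median(dmso))
    if x_dmso == 0:
        raise DegeneratePlateError(
            f"plate {plate.barcode}: median DMSO luminescence is zero")
    drug = plate.wells[plate.wells["role"] == "DRUG"]
    out = drug[["drug_id", "dose_uM", "replicate"]].copy()
    out["FA"] = 1.0 - drug["rlu"].to_numpy(float) / x_dmso
    return out.reset_index(drop=True)


def normalize_screen(plates: Iterable[Plate]) -> pd.DataFrame:
    """Normalize a list of plates into one long table.

    Columns: drug_id, model, dose_uM, replicate, FA.  The model id is
    decoded from each plate barcode.
    """
    frames = []
    for plate in plates:
        df = normalize(plate)
        df.insert(1, "model", model_from_barcode(plate.barcode))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def z_prime(plate: Plate) -> float:
    """Z-prime assay-quality statistic from on-plate controls (raw RLU)."""
    veh = plate.rlu("DMSO")
    pos = plate.rlu("POSCON")
    if veh.size < 2 or pos.size < 2:
        raise InsufficientDataError(
            f"plate {plate.barcode}: need >= 2 DMSO and >= 2 POSCON wells")
    mu_v, mu_p = veh.mean(), pos.mean()
    if mu_v == mu_p:
        raise PdxScreenError(
            f"plate {plate.barcode}: control means identical, "
            "Z-prime undefined")
    return 1.0 - 3.0 * (pos.std(ddof=1) + veh.std(ddof=1)) / abs(mu_p - mu_v)


def msr(replicate_log10_potencies) -> float:
    """Minimum significance ratio from replicate log10 potencies."""
    s_vals = np.asarray(replicate_log10_potencies, dtype=float)
    s_vals = s_vals[np.isfinite(s_vals)]
    if s_vals.size < 2:
        raise InsufficientDataError(
            "MSR needs >= 2 replicate potency estimates")
    s = float(np.std(s_vals, ddof=1))
    return 10.0 ** (2.0 * math.sqrt(2.0) * s)


def ddct_human_content(ct_human_sample: float, ct_mouse_sample: float,
                       ct_human_ref: float, ct_mouse_ref: float) -> float:
    """Fraction of human DNA from qPCR Ct values (ddCt method).

    The relative human:mouse abundance is 2**(-ddCt); the returned value is
    that ratio expressed as a fraction ratio / (1 + ratio).
    """
    cts = (ct_human_sample, ct_mouse_sample, ct_human_ref, ct_mouse_ref)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_human_sample - ct_mouse_sample) - (ct_human_ref - ct_mouse_ref)
    ratio = 2.0 ** (-ddct)
    return ratio / (1.0 + ratio)


# ---------------------------------------------------------------------------
# screen-level QC report
# ---------------------------------------------------------------------------

def replicate_potencies(normalized: pd.DataFrame,
                        dose_range_uM=None) -> pd.DataFrame:
    """Per-replicate log10 potency (log10 IC50) for every drug-model pair.

    Each technical replicate's FA-vs-dose points are fitted independently
    with the cascade model; the log10 of the 0.5-crossing dose is the
    potency.  Replicates whose curve never crosses 0.5 yield NaN.
    """
    from . import doseresp  # local import: avoid cycle at module load

    rows = []
    grouped = normalized.groupby(["model", "drug_id", "replicate"],
                                 sort=True)
    for (model, drug, rep), grp in grouped:
        x = np.log10(grp["dose_uM"].to_numpy(float))
        try:
            fit = doseresp.fit_cascade(x, grp["FA"].to_numpy(float),
                                       drug_id=drug, model_id=model,
                                       dose_range_uM=dose_range_uM)
            pot = math.log10(fit.ic50_uM) if fit.ic50_uM else math.nan
        except InsufficientDataError:
            pot = math.nan
        rows.append({"model": model, "drug_id": drug, "replicate": rep,
                     "log10_potency": pot})
    return pd.DataFrame(rows)


def qc_report(plates: Iterable[Plate],
              potencies: Optional[pd.DataFrame] = None) -> dict:
    """Screen-level QC: per-plate Z-prime and per-drug MSR.

    ``potencies`` is the output of :func:`replicate_potencies`; when
    omitted the MSR section is skipped.
    """
    zp = {p.barcode: z_prime(p) for p in plates}
    report = {
        "z_prime_per_plate": zp,
        "mean_z_prime": float(np.mean(list(zp.values()))),
    }
    if potencies is not None:
        msrs = {}
        for (model, drug), grp in potencies.groupby(["model", "drug_id"]):
            vals = grp["log10_potency"].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size >= 2:
                msrs[f"{model}:{drug}"] = msr(vals)
        report["msr_per_drug"] = msrs
        report["mean_msr"] = (float(np.mean(list(msrs.values())))
                              if msrs else math.nan)
    return report
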