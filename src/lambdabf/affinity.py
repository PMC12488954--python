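"""Affinity bookkeeping and Apo–Holo calibration.

Raw computed absolute binding free energies start from the ligand-bound
(Holo) receptor conformation and, because the receptor is held near that
conformation throughout the cycle, systematically overestimate binding by
the Apo→Holo reorganization free energy. The calibration applied here
absorbs that common offset into a constant shift

    ΔG_shift = (Σ_i G_i^Exp − Σ_i G_i^Comp) / N

computed over the ligands with measured affinities, so that the mean of
the shifted computed values equals the mean of the experimental ones.

The module ships the benzimidazole/riboswitch-like-RNA dataset of 19
ligands (dissociation constants, experimental ΔG, raw and shifted
computed ΔG with replica SEMs) as a plain TSV fixture and provides the
K_D ↔ ΔG conversions, replica statistics, binder classification and
correlation metrics used to evaluate it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .units import KB

#: temperature used for K_D → ΔG conversion (reproduces the dataset's
#: printed experimental ΔG to 2 d.p.); simulations themselves ran at 300 K.
CONVERSION_TEMPERATURE = 298.15

#: experimental one-sided ΔG bound assigned to non-binders (kcal/mol)
EXP_BOUND = -5.04


class InclusionError(ValueError):
    """A record without a point experimental ΔG entered the calibration."""


def kd_to_delta_g(kd_molar: float,
                  temperature: float = CONVERSION_TEMPERATURE) -> float:
    """ΔG = R·T·ln(K_D/c°) with c° = 1 M; K_D in molar, result kcal/mol."""
    if kd_molar <= 0:
        raise ValueError("K_D must be > 0")
    return KB * temperature * float(np.log(kd_molar))

def delta_g_to_kd(dg: float,
                  temperature: float = CONVERSION_TEMPERATURE) -> float:
    """Inverse of :func:`kd_to_delta_g`; returns K_D in molar."""
    return float(np.exp(dg / (KB * temperature)))


def delta_delta_g(kd_a_molar: float, kd_b_molar: float,
                  temperature: float = CONVERSION_TEMPERATURE) -> float:
    """Affinity difference R·T·ln(K_D_b/K_D_a) (kcal/mol)."""
    if kd_a_molar <= 0 or kd_b_molar <= 0:
        raise ValueError("K_D values must be > 0")
    # difference of logs, so swapping arguments flips the sign exactly
    return KB * temperature * float(np.log(kd_b_molar) - np.log(kd_a_molar))


def replica_stats(values) -> tuple[float, float]:
    """(mean, SEM) over replicas; SEM uses the sample std (ddof=1)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two replicas")
    return float(values.mean()), float(values.std(ddof=1)
                                       / np.sqrt(len(values)))


@dataclass
class LigandRecord:
    """One dataset row. ``kd_um`` is a lower bound when ``kd_is_bound``;
    such records carry ``dg_exp`` as a one-sided bound, never as a point
    value, and are excluded from calibration and correlation metrics."""

    ligand_id: int
    kd_um: float
    kd_is_bound: bool
    construct: str
    dg_exp: float
    dg_comp_table: float | None
    dg_raw: float | None
    sem: float | None
    note: str = "."

    @property
    def has_abfe(self) -> bool:
        return self.dg_raw is not None and np.isfinite(self.dg_raw)

    @property
    def is_binder(self) -> bool:
        return not self.kd_is_bound


def load_dataset(path: str | Path | None = None) -> list[LigandRecord]:
    """Load the embedded ligand dataset (or a file in the same format)."""
    if path is None:
        text = (importlib.resources.files("lambdabf") / "data" /
                "benzimidazole_affinities.tsv").read_text()
    else:
        text = Path(path).read_text()
    df = pd.read_csv(StringIO(text), sep="\t", comment="#",
                     na_values=["NA"])
    records = []
    for row in df.itertuples(index=False):
        records.append(LigandRecord(
            ligand_id=int(row.id),
            kd_um=float(row.kd_um),
            kd_is_bound=bool(int(row.kd_is_bound)),
            construct=str(row.construct),
            dg_exp=float(row.dg_exp),
            dg_comp_table=(None if pd.isna(row.dg_comp_table)
                           else float(row.dg_comp_table)),
            dg_raw=None if pd.isna(row.dg_raw) else float(row.dg_raw),
            sem=None if pd.isna(row.sem) else float(row.sem),
            note=str(row.note),
        ))
    return records


def save_dataset(records: list[LigandRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.ligand_id,
            "kd_um": r.kd_um,
            "kd_is_bound": int(r.kd_is_bound),
            "construct": r.construct,
            "dg_exp": r.dg_exp,
            "dg_comp_table": "NA" if r.dg_comp_table is None
            else r.dg_comp_table,
            "dg_raw": "NA" if r.dg_raw is None else r.dg_raw,
            "sem": "NA" if r.sem is None else r.sem,
            "note": r.note,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_binders(records: list[LigandRecord],
                     exp_bound: float = EXP_BOUND) -> dict[int, dict]:
    """Experimental binder/non-binder labels plus computed predictions.

    A record is an experimental non-binder iff its K_D is a lower bound.
    ``predicted_non_binder`` flags ligands whose shifted computed ΔG lies
    above the experimental bound; ``no_abfe`` flags records without an
    alchemical result.
    """
    out = {}
    for r in records:
        out[r.ligand_id] = {
            "binder": r.is_binder,
            "predicted_non_binder": (r.dg_comp_table is not None
                                     and r.dg_comp_table > exp_bound),
            "no_abfe": not r.has_abfe,
        }
    return out


def compute_shift(records: list[LigandRecord]) -> tuple[float, float]:
    """ΔG_shift = (Σ G_exp − Σ G_raw)/N over the included records.

    Returns (shift, uncertainty); the uncertainty propagates the
    per-ligand replica SEMs in quadrature divided by N. Records without a
    point experimental value (non-binders) or without an alchemical
    result may not be included.
    """
    if not records:
        raise InclusionError("no records included in the calibration")
    for r in records:
        if r.kd_is_bound:
            raise InclusionError(
                f"ligand {r.ligand_id} has only a K_D bound; it cannot "
                "enter the calibration")
        if not r.has_abfe:
            raise InclusionError(
                f"ligand {r.ligand_id} has no computed ΔG")
    exp = np.array([r.dg_exp for r in records])
    raw = np.array([r.dg_raw for r in records])
    sems = np.array([0.0 if r.sem is None else r.sem for r in records])
    shift = float(exp.mean() - raw.mean())
    err = float(np.sqrt(np.sum(sems ** 2)) / len(records))
    return shift, err


def apply_shift(records: list[LigandRecord], shift: float) -> dict[int, float]:
    """Shifted computed ΔG per ligand: ΔG_comp = ΔG_raw + ΔG_shift."""
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    return {r.ligand_id: r.dg_raw + shift for r in records if r.has_abfe}


def correlation_metrics(exp, comp) -> tuple[float, float, float]:
    """(Pearson r, RMSE, MAE) between experimental and computed ΔG."""
    exp = np.asarray(exp, dtype=float)
    comp = np.asarray(comp, dtype=float)
    if exp.shape != comp.shape or len(exp) < 3:
        raise ValueError("need two equal-length vectors of ≥3 values")
    if exp.std() == 0 or comp.std() == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    r = float(np.corrcoef(exp, comp)[0, 1])
    rmse = float(np.sqrt(np.mean((exp - comp) ** 2)))
    mae = float(np.mean(np.abs(exp - comp)))
    return r, rmse, mae


@dataclass
class CalibrationResult:
    shift: float
    shift_error: float
    included_ids: list[int]
    shifted: dict[int, float]
    pearson_r: float
    rmse: float
    mae: float
    metrics_source: str = "published_table"

    def report(self) -> str:
        lines = [
            f"calibration over ligands {self.included_ids}",
            f"dG_shift = {self.shift:.2f} ± {self.shift_error:.2f} kcal/mol",
            f"Pearson r = {self.pearson_r:.2f}  RMSE = {self.rmse:.2f}  "
            f"MAE = {self.mae:.2f} kcal/mol",
        ]
        for lid in self.included_ids:
            lines.append(f"  ligand {lid}: shifted dG_comp = "
                         f"{self.shifted[lid]:+.2f} kcal/mol")
        return "\n".join(lines)


def calibrate(records: list[LigandRecord],
              include_ids: list[int] | None = None,
              metrics_from_table: bool = True) -> CalibrationResult:
    """Full calibration: shift, shifted values and correlation metrics.

    ``include_ids`` restricts the calibration set (default: all binders
    with an alchemical result). ``metrics_from_table`` computes the
    correlation metrics from the published shifted column of the dataset
    when present (the column the published scatter metrics derive from);
    otherwise they are recomputed from raw + shift.
    """
    by_id = {r.ligand_id: r for r in records}
    if include_ids is None:
        included = [r for r in records if r.is_binder and r.has_abfe]
    else:
        included = [by_id[i] for i in include_ids]
    shift, err = compute_shift(included)
    shifted = apply_shift(included, shift)
    exp = [r.dg_exp for r in included]
    if metrics_from_table and all(r.dg_comp_table is not None
                                  for r in included):
        comp = [r.dg_comp_table for r in included]
        source = "published_table"
    else:
        comp = [shifted[r.ligand_id] for r in included]
        source = "raw_plus_shift"
    r_, rmse, mae = correlation_metrics(exp, comp)
    return CalibrationResult(shift=shift, shift_error=err,
                             included_ids=[r.ligand_id for r in included],
                             shifted=shifted, pearson_r=r_, rmse=rmse,
                             mae=mae, metrics_source=source)
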