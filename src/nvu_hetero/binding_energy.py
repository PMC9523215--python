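"""MM/GBSA bookkeeping: window-averaged binding free energy and screening.

The binding free energy is the difference of window-averaged energies,
dGbind = G(complex) - (G(receptor) + G(ligand)), decomposed into internal
(bond + angle + torsion), van der Waals, electrostatic, generalized-Born
polar solvation and nonpolar surface-area terms. The nonpolar term is a
fixed surface-tension coefficient times the solvent-accessible surface
area: GSA = 0.0072 * SASA (kcal/mol per A^2). No energies are computed
from structures here; inputs are pre-tabulated per-frame components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

SURFACE_TENSION = 0.0072  # kcal/mol per A^2
DEFAULT_WINDOW = (20.0, 30.0)  # ns
DEFAULT_SCREEN_THRESHOLD = -6.5  # kcal/mol

_MM_COMPONENTS = ("Ebond", "Eangle", "Etorsion", "EVDW", "Eelec", "EGB")
DELTA_TERMS = ("dE_internal", "dE_vdw", "dE_elec", "dG_gb", "dG_sa")


@dataclass
class EnergyTable:
    """Per-frame component energies for one role (complex/receptor/ligand).

    The frame table must carry ``time_ns``, the molecular-mechanics and GB
    columns, and exactly one of ``GSA`` (kcal/mol) or ``SASA`` (A^2).
    """

    role: str
    frames: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ("complex", "receptor", "ligand"):
            raise InputError(f"unknown role {self.role!r}")
        cols = set(self.frames.columns)
        missing = {"time_ns", *_MM_COMPONENTS} - cols
        if missing:
            raise FormatError(f"{self.role} table missing columns {sorted(missing)}")
        has_sa = {"GSA", "SASA"} & cols
        if len(has_sa) != 1:
            raise FormatError(
                f"{self.role} table must have exactly one of GSA or SASA")
        t = self.frames["time_ns"].to_numpy()
        if len(t) and (np.diff(t) < 0).any():
            raise FormatError(f"{self.role} frames are not time-ordered")

    def window(self, t0: float, t1: float) -> pd.DataFrame:
        t = self.frames["time_ns"]
        sel = self.frames[(t >= t0) & (t <= t1)]
        if sel.empty:
            raise InputError(
                f"window [{t0}, {t1}] ns covers no frames of the {self.role} table")
        return sel


@dataclass
class BindingEnergy:
    """Aggregated dGbind with its five-term decomposition."""

    dg_bind: float
    terms: dict            # DELTA_TERMS -> kcal/mol
    window_ns: tuple
    standard_errors: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"dG_bind": self.dg_bind, **self.terms,
                "window_ns": list(self.window_ns)}


def nonpolar_term(sasa) -> float:
    """Nonpolar solvation free energy (kcal/mol) from SASA (A^2)."""
    sasa = np.asarray(sasa, dtype=float)
    if (sasa < 0).any():
        raise InputError("SASA must be non-negative")
    out = SURFACE_TENSION * sasa
    return float(out) if out.ndim == 0 else out


def _per_frame_terms(table: EnergyTable, t0: float, t1: float) -> pd.DataFrame:
    w = table.window(t0, t1)
    gsa = w["GSA"].to_numpy() if "GSA" in w.columns else nonpolar_term(w["SASA"].to_numpy())
    return pd.DataFrame({
        "dE_internal": w["Ebond"].to_numpy() + w["Eangle"].to_numpy()
                       + w["Etorsion"].to_numpy(),
        "dE_vdw": w["EVDW"].to_numpy(),
        "dE_elec": w["Eelec"].to_numpy(),
        "dG_gb": w["EGB"].to_numpy(),
        "dG_sa": gsa,
    })


def mmgbsa(complex_t: EnergyTable, receptor_t: EnergyTable, ligand_t: EnergyTable,
           window: tuple = DEFAULT_WINDOW) -> BindingEnergy:
    """Window-averaged dGbind = complex - (receptor + ligand), per term.

    Frame grids need not match across the three tables; only window means
    are combined. Per-term standard errors combine the three tables'
    standard errors of the mean in quadrature.
    """
    t0, t1 = window
    if t0 > t1:
        raise InputError("window start must not exceed its end")
    parts = {role: _per_frame_terms(tab, t0, t1)
             for role, tab in (("complex", complex_t), ("receptor", receptor_t),
                               ("ligand", ligand_t))}
    terms, sems = {}, {}
    for term in DELTA_TERMS:
        means = {r: parts[r][term].mean() for r in parts}
        terms[term] = float(means["complex"] - (means["receptor"] + means["ligand"]))
        sems[term] = float(np.sqrt(sum(
            parts[r][term].std(ddof=1) ** 2 / len(parts[r]) if len(parts[r]) > 1 else 0.0
            for r in parts)))
    dg = float(sum(terms.values()))
    return BindingEnergy(dg, terms, (float(t0), float(t1)), sems)


def screen_binders(results: dict, threshold: float = DEFAULT_SCREEN_THRESHOLD) -> list:
    """Names whose dGbind is strictly below the threshold (order preserved)."""
    for name, v in results.items():
        if not np.isfinite(v):
            raise InputError(f"non-finite binding energy for {name!r}")
    return [name for name, v in results.items() if v < threshold]


def read_energy_table(path, role: str) -> EnergyTable:
    """Read a per-frame component TSV (header: time_ns, Ebond, ..., SASA|GSA)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:
        raise FormatError(f"malformed energy table {path}: {e}") from e
    return EnergyTable(role, df)


def write_energy_table(table: EnergyTable, path) -> None:
    table.frames.to_csv(Path(path), sep="\t", index=False)
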