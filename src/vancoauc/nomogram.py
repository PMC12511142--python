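"""AUC nomograms: per-regimen lookup tables over (Vd, Ctrough,ss).

Each nomogram fixes a maintenance regimen (dose, interval, infusion time)
and tabulates, for every combination of distribution volume (20-80 L in
5 L steps) and steady-state trough (5-25 mg/L in 1 mg/L steps), the AUC24
implied by the one-compartment model: the cell's Ke is solved from the
trough closed form and AUC24 = daily dose / (Ke * Vd).  Cells are banded by
the vancomycin therapeutic target: white for 400 <= AUC <= 600 (the
AUC/MIC goal at MIC = 1 mg/L), light grey for the 350-400 and 600-650
margins, dark grey otherwise.

At the bedside the table is read with the *apparent* volume Vd,app =
first dose / first peak in place of Vd: :func:`lookup_auc_nmg` snaps both
coordinates to the nearest grid line (ties round up) and returns the cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from vancoauc.estimators import NonConvergenceError, solve_ke_from_trough
from vancoauc.pk_core import DomainError, DosingRegimen
from vancoauc.twocomp import infusion_duration

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_DOSES_G",
    "CANONICAL_TAUS_H",
    "LookupResult",
    "NomogramGrid",
    "band_for_auc",
    "build_all_nomograms",
    "build_nomogram",
    "export_nomogram",
    "lookup_auc_nmg",
    "read_nomogram",
]

#: The 15 canonical regimens: every dose crossed with every interval.
CANONICAL_DOSES_G = (0.5, 0.75, 1.0, 1.25, 1.5)
CANONICAL_TAUS_H = (8.0, 12.0, 24.0)

VD_AXIS = np.arange(20.0, 80.0 + 2.5, 5.0)  # L, 13 values
CTROUGH_AXIS = np.arange(5.0, 25.0 + 0.5, 1.0)  # mg/L, 21 values

BAND_WHITE = "white"  # 400 <= AUC <= 600: therapeutic
BAND_LIGHT = "light"  # 350 <= AUC < 400 or 600 < AUC <= 650: marginal
BAND_DARK = "dark"  # anything else
BAND_MISSING = "missing"  # cell not attainable by the model


def band_for_auc(auc: float) -> str:
    """Therapeutic band of an AUC24 value (mg*h/L)."""
    if math.isnan(auc):
        return BAND_MISSING
    if 400.0 <= auc <= 600.0:
        return BAND_WHITE
    if 350.0 <= auc < 400.0 or 600.0 < auc <= 650.0:
        return BAND_LIGHT
    return BAND_DARK


@dataclass(frozen=True)
class NomogramGrid:
    """An AUC lookup table for one maintenance regimen.

    ``auc`` is a (len(vd_axis), len(ctrough_axis)) matrix in mg*h/L with
    NaN for unattainable cells; ``band`` holds the matching band labels.
    """

    dose_mg: float
    tau: float
    t_in: float
    vd_axis: np.ndarray = field(default_factory=lambda: VD_AXIS.copy())
    ctrough_axis: np.ndarray = field(default_factory=lambda: CTROUGH_AXIS.copy())
    auc: np.ndarray | None = None
    band: np.ndarray | None = None
    canonical: bool = True

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NomogramGrid):
            return NotImplemented
        return (
            (self.dose_mg, self.tau, self.t_in, self.canonical)
            == (other.dose_mg, other.tau, other.t_in, other.canonical)
            and np.array_equal(self.vd_axis, other.vd_axis)
            and np.array_equal(self.ctrough_axis, other.ctrough_axis)
            and np.array_equal(self.auc, other.auc, equal_nan=True)
            and np.array_equal(self.band, other.band)
        )


def _regimen_for(dose_mg: float, tau: float, t_in: float | None) -> DosingRegimen:
    t_in = infusion_duration(dose_mg) if t_in is None else t_in
    # first_dose is irrelevant to the steady-state trough; mirror the MD.
    return DosingRegimen(
        first_dose=dose_mg, maintenance_dose=dose_mg, tau=tau, t_in=t_in
    )


def build_nomogram(
    dose_mg: float,
    tau: float,
    t_in: float | None = None,
    vd_axis: np.ndarray = VD_AXIS,
    ctrough_axis: np.ndarray = CTROUGH_AXIS,
) -> NomogramGrid:
    """Tabulate AUC24 over the (Vd, Ctrough,ss) grid for one regimen.

    For every cell, Ke is solved from the steady-state trough equation and
    AUC24 = MD/(Ke*Vd) * 24/tau.  Cells whose trough target lies outside
    the attainable range are recorded as missing (NaN), never fabricated.
    Regimens outside the 15 canonical dose/interval combinations are
    allowed but flagged non-canonical.
    """
    canonical = (
        round(dose_mg) in {int(d * 1000) for d in CANONICAL_DOSES_G}
        and tau in CANONICAL_TAUS_H
    )
    if not canonical:
        logger.warning("building non-canonical nomogram: %s mg q%sh", dose_mg, tau)
    regimen = _regimen_for(dose_mg, tau, t_in)
    auc = np.full((len(vd_axis), len(ctrough_axis)), np.nan)
    band = np.full(auc.shape, BAND_MISSING, dtype=object)
    for i, vd in enumerate(vd_axis):
        for j, ct in enumerate(ctrough_axis):
            try:
                ke = solve_ke_from_trough(regimen, float(vd), float(ct))
            except NonConvergenceError as exc:
                logger.warning(
                    "cell (Vd=%s L, Ct=%s mg/L) not attainable: %s", vd, ct, exc
                )
                continue
            auc[i, j] = dose_mg / (ke * vd) * 24.0 / tau
            band[i, j] = band_for_auc(auc[i, j])
    return NomogramGrid(
        dose_mg=dose_mg,
        tau=tau,
        t_in=regimen.t_in,
        vd_axis=np.asarray(vd_axis, dtype=float),
        ctrough_axis=np.asarray(ctrough_axis, dtype=float),
        auc=auc,
        band=band,
        canonical=canonical,
    )


def build_all_nomograms() -> dict[tuple[float, float], NomogramGrid]:
    """Build the 15 canonical nomograms, keyed by (dose in mg, tau in h)."""
    return {
        (d * 1000.0, tau): build_nomogram(d * 1000.0, tau)
        for d in CANONICAL_DOSES_G
        for tau in CANONICAL_TAUS_H
    }


@dataclass(frozen=True)
class LookupResult:
    """Outcome of a nomogram cell lookup."""

    auc: float  # NaN when the snapped cell is missing
    band: str
    cell_vd: float
    cell_ctrough: float
    out_of_range: bool  # an input lay outside the axis span and was clamped

    @property
    def evaluable(self) -> bool:
        return self.band != BAND_MISSING


def _snap(value: float, axis: np.ndarray) -> tuple[int, bool]:
    """Nearest axis index with ties rounding up; clamps out-of-span inputs."""
    lo, hi = axis[0], axis[-1]
    clamped = value < lo or value > hi
    v = min(max(value, lo), hi)
    step = axis[1] - axis[0]
    idx = int(math.floor((v - lo) / step + 0.5))  # floor(x+0.5): ties go up
    return min(idx, len(axis) - 1), clamped


def lookup_auc_nmg(
    vd_app: float, ctrough_ss: float, grid: NomogramGrid
) -> LookupResult:
    """Read the nomogram at the nearest (Vd, Ctrough,ss) cell.

    Both inputs snap to the closest axis value (ties round up — e.g.
    52.5 L lands on 55 L); inputs outside the tabulated span clamp to the
    boundary and set ``out_of_range``.  A missing cell yields an explicit
    non-evaluable result rather than a number.
    """
    if not vd_app > 0 or not ctrough_ss > 0:
        raise DomainError("vd_app and ctrough_ss must be > 0")
    if grid.auc is None:
        raise DomainError("grid has not been built")
    i, clamp_v = _snap(vd_app, grid.vd_axis)
    j, clamp_c = _snap(ctrough_ss, grid.ctrough_axis)
    out = clamp_v or clamp_c
    if out:
        logger.info(
            "lookup (%s L, %s mg/L) outside nomogram span; clamped", vd_app, ctrough_ss
        )
    return LookupResult(
        auc=float(grid.auc[i, j]),
        band=str(grid.band[i, j]),
        cell_vd=float(grid.vd_axis[i]),
        cell_ctrough=float(grid.ctrough_axis[j]),
        out_of_range=out,
    )


# --- persistence ----------------------------------------------------------

def export_nomogram(grid: NomogramGrid, path: str | Path, figure: bool = False) -> None:
    """Write a grid as CSV (metadata line, axis header, Vd rows x Ctrough
    columns) with the band matrix appended; round-trips bit-identically
    through :func:`read_nomogram`.  ``figure=True`` also renders a PNG
    heat map alongside.
    """
    if grid.auc is None:
        raise DomainError("grid has not been built")
    path = Path(path)
    lines = [
        f"# dose_mg={grid.dose_mg!r},tau={grid.tau!r},t_in={grid.t_in!r},"
        f"canonical={grid.canonical}"
    ]
    header = "vd_L\\ctrough_mg_per_L," + ",".join(
        repr(float(c)) for c in grid.ctrough_axis
    )
    lines.append(header)
    for i, vd in enumerate(grid.vd_axis):
        lines.append(
            repr(float(vd)) + "," + ",".join(repr(float(a)) for a in grid.auc[i])
        )
    lines.append("# band")
    lines.append(header)
    for i, vd in enumerate(grid.vd_axis):
        lines.append(repr(float(vd)) + "," + ",".join(grid.band[i]))
    path.write_text("\n".join(lines) + "\n")
    if figure:
        _render_figure(grid, path.with_suffix(".png"))


def read_nomogram(path: str | Path) -> NomogramGrid:
    """Read a grid written by :func:`export_nomogram`."""
    lines = Path(path).read_text().splitlines()
    meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split(","))
    ctrough_axis = np.array([float(v) for v in lines[1].split(",")[1:]])
    n_band_header = lines.index("# band")
    vd_axis, auc_rows = [], []
    for line in lines[2:n_band_header]:
        cells = line.split(",")
        vd_axis.append(float(cells[0]))
        auc_rows.append([float(v) for v in cells[1:]])
    band_rows = [line.split(",")[1:] for line in lines[n_band_header + 2 :]]
    return NomogramGrid(
        dose_mg=float(meta["dose_mg"]),
        tau=float(meta["tau"]),
        t_in=float(meta["t_in"]),
        vd_axis=np.array(vd_axis),
        ctrough_axis=ctrough_axis,
        auc=np.array(auc_rows),
        band=np.array(band_rows, dtype=object),
        canonical=meta["canonical"] == "True",
    )


def _render_figure(grid: NomogramGrid, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shade = {BAND_WHITE: 1.0, BAND_LIGHT: 0.7, BAND_DARK: 0.35, BAND_MISSING: 0.0}
    img = np.vectorize(shade.get)(grid.band.T)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.imshow(
        img,
        origin="lower",
        cmap="gray",
        vmin=0,
        vmax=1,
        aspect="auto",
        extent=(
            grid.vd_axis[0] - 2.5,
            grid.vd_axis[-1] + 2.5,
            grid.ctrough_axis[0] - 0.5,
            grid.ctrough_axis[-1] + 0.5,
        ),
    )
    for i, vd in enumerate(grid.vd_axis):
        for j, ct in enumerate(grid.ctrough_axis):
            if not math.isnan(grid.auc[i, j]):
                ax.text(
                    vd, ct, f"{grid.auc[i, j]:.0f}", ha="center", va="center",
                    fontsize=5,
                )
    ax.set_xlabel("Vd (L)")
    ax.set_ylabel("Ctrough,ss (mg/L)")
    ax.set_title(f"{grid.dose_mg / 1000:g} g q{grid.tau:g}h (t_in {grid.t_in:g} h)")
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)
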