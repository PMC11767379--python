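"""File formats: MTZ / structure-factor mmCIF in, CCP4 maps and CSV out.

All parsing and writing is delegated to gemmi; this module only adapts
between gemmi objects and the package's in-memory types.  The free-set
flag convention on input is 0 = free (the common MTZ convention).
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .grid import DensityGrid, PhasedAmplitudes
from .lattice import GridSpec, UnitCell
from .modify import MetricsRecord, ReferenceHistogram
from .reflections import FREE, MISSING, WORK, ReflectionSet

__all__ = [
    "read_reflections",
    "write_reflections_cif",
    "write_map",
    "read_map",
    "write_phases_cif",
    "write_phases_mtz",
    "write_metrics_csv",
    "read_histogram_csv",
    "write_histogram_csv",
]


def _cell_from_gemmi(cell: gemmi.UnitCell) -> UnitCell:
    return UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


def read_reflections(path: str | Path) -> tuple[ReflectionSet, UnitCell, str]:
    """Read amplitudes from MTZ or SF-mmCIF.

    Returns (reflections, cell, space-group symbol).  MTZ files must
    carry FP (amplitude) and may carry SIGFP and a FREE flag column
    (0 = free); mmCIF files must carry _refln.F_meas_au.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mtz":
        return _read_mtz(path)
    if suffix in (".cif", ".ent", ".mmcif"):
        return _read_sf_cif(path)
    raise ValueError(f"unsupported reflection file format: {path.suffix!r}")


def _read_mtz(path: Path) -> tuple[ReflectionSet, UnitCell, str]:
    mtz = gemmi.read_mtz_file(str(path))
    labels = [c.label for c in mtz.columns]
    if "FP" not in labels:
        raise ValueError(f"MTZ file {path} lacks the amplitude column 'FP'")
    arr = mtz.array
    col = {lab: i for i, lab in enumerate(labels)}
    hkl = arr[:, [col["H"], col["K"], col["L"]]].astype(np.int64)
    f_obs = arr[:, col["FP"]].astype(np.float64)
    sigma = arr[:, col["SIGFP"]].astype(np.float64) if "SIGFP" in col else None
    cell = _cell_from_gemmi(mtz.cell)
    refl = ReflectionSet.from_amplitudes(hkl, np.nan_to_num(f_obs), cell,
                                         sigma=sigma,
                                         missing=~np.isfinite(f_obs))
    free_col = next((lab for lab in labels
                     if lab.upper() in ("FREE", "FREER", "FREERFLAG", "R-FREE-FLAGS")),
                    None)
    if free_col is not None:
        flags = arr[:, col[free_col]]
        refl.label[(flags == 0) & (refl.label == WORK)] = FREE
    return refl, cell, mtz.spacegroup.hm if mtz.spacegroup else "P1"


def _read_sf_cif(path: Path) -> tuple[ReflectionSet, UnitCell, str]:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    h = block.find_loop("_refln.index_h")
    k = block.find_loop("_refln.index_k")
    l = block.find_loop("_refln.index_l")
    f = block.find_loop("_refln.F_meas_au")
    if not h or not f:
        raise ValueError(
            f"{path} lacks _refln.index_h / _refln.F_meas_au records")
    hkl = np.array([[int(a), int(b), int(c)] for a, b, c in zip(h, k, l)],
                   dtype=np.int64)
    missing = np.array([v in ("?", ".") for v in f])
    f_obs = np.array([0.0 if m else float(v) for v, m in zip(f, missing)])
    sig_loop = block.find_loop("_refln.F_meas_sigma_au")
    sigma = (np.array([0.0 if v in ("?", ".") else float(v) for v in sig_loop])
             if sig_loop else None)
    cell_vals = []
    for tag in ("a", "b", "c", "angle_alpha", "angle_beta", "angle_gamma"):
        v = block.find_value(f"_cell.length_{tag}") if tag in ("a", "b", "c") \
            else block.find_value(f"_cell.{tag}")
        if v is None:
            raise ValueError(f"{path} lacks _cell.{tag}")
        cell_vals.append(float(v))
    cell = UnitCell(*cell_vals)
    symbol = block.find_value("_symmetry.space_group_name_H-M") or "P1"
    symbol = symbol.strip("'\"")
    refl = ReflectionSet.from_amplitudes(hkl, f_obs, cell, sigma=sigma,
                                         missing=missing)
    status = block.find_loop("_refln.status")
    if status:
        free = np.array([v == "f" for v in status])
        refl.label[free & (refl.label == WORK)] = FREE
    return refl, cell, symbol


def write_reflections_cif(refl: ReflectionSet, cell: UnitCell,
                          path: str | Path, symbol: str = "P1") -> None:
    """Write amplitudes as a structure-factor mmCIF file."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("reflections")
    block.set_pair("_cell.length_a", f"{cell.a:.6g}")
    block.set_pair("_cell.length_b", f"{cell.b:.6g}")
    block.set_pair("_cell.length_c", f"{cell.c:.6g}")
    block.set_pair("_cell.angle_alpha", f"{cell.alpha:.6g}")
    block.set_pair("_cell.angle_beta", f"{cell.beta:.6g}")
    block.set_pair("_cell.angle_gamma", f"{cell.gamma:.6g}")
    block.set_pair("_symmetry.space_group_name_H-M", gemmi.cif.quote(symbol))
    loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l",
                                       "F_meas_au", "status"])
    for i in range(len(refl)):
        label = refl.label[i]
        status = {WORK: "o", FREE: "f"}.get(int(label), "<")
        value = "?" if label == MISSING else f"{refl.f_obs[i]:.6g}"
        loop.add_row([str(refl.hkl[i, 0]), str(refl.hkl[i, 1]),
                      str(refl.hkl[i, 2]), value, status])
    doc.write_file(str(path))


def write_map(g: DensityGrid, path: str | Path) -> None:
    """Write a density grid as a CCP4/MRC mode-2 map with cell metadata."""
    grid = gemmi.FloatGrid(*g.spec.dims)
    grid.set_unit_cell(g.spec.cell.to_gemmi())
    grid.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(grid.array)[:] = g.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path, d_min: float = 0.0) -> DensityGrid:
    """Read a CCP4/MRC map back onto a DensityGrid."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    grid = ccp4.grid
    cell = _cell_from_gemmi(grid.unit_cell)
    spec = GridSpec(dims=tuple(np.asarray(grid.array).shape), cell=cell,
                    d_min=d_min if d_min > 0 else min(cell.lengths))
    return DensityGrid(spec, np.asarray(grid.array, dtype=np.float64))


def write_phases_cif(amps: PhasedAmplitudes, cell: UnitCell,
                     path: str | Path, symbol: str = "P1") -> None:
    """Write phased amplitudes as mmCIF (_refln.F_calc_au / phase_calc)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("phases")
    block.set_pair("_cell.length_a", f"{cell.a:.6g}")
    block.set_pair("_cell.length_b", f"{cell.b:.6g}")
    block.set_pair("_cell.length_c", f"{cell.c:.6g}")
    block.set_pair("_cell.angle_alpha", f"{cell.alpha:.6g}")
    block.set_pair("_cell.angle_beta", f"{cell.beta:.6g}")
    block.set_pair("_cell.angle_gamma", f"{cell.gamma:.6g}")
    block.set_pair("_symmetry.space_group_name_H-M", gemmi.cif.quote(symbol))
    loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l",
                                       "F_calc_au", "phase_calc"])
    for i in range(len(amps)):
        loop.add_row([str(amps.hkl[i, 0]), str(amps.hkl[i, 1]),
                      str(amps.hkl[i, 2]), f"{amps.amplitude[i]:.6g}",
                      f"{amps.phase[i]:.4f}"])
    doc.write_file(str(path))


def write_phases_mtz(amps: PhasedAmplitudes, cell: UnitCell,
                     path: str | Path, symbol: str = "P1") -> None:
    """Write phased amplitudes as MTZ columns FC / PHIC."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup(symbol)
    mtz.set_cell_for_all(cell.to_gemmi())
    mtz.add_dataset("phases")
    mtz.add_column("FC", "F")
    mtz.add_column("PHIC", "P")
    data = np.column_stack([amps.hkl.astype(np.float64), amps.amplitude,
                            amps.phase])
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def write_metrics_csv(traces: list[list[MetricsRecord]], path: str | Path,
                      elite_iteration: list[int | None] | None = None) -> None:
    """Per-iteration metrics, one row per (rank, iteration)."""
    rows = []
    for rank, trace in enumerate(traces):
        elite_at = (elite_iteration[rank] if elite_iteration else None)
        for rec in trace:
            rows.append({
                "iteration": rec.iteration,
                "rank": rank,
                "Rwork": rec.rwork,
                "Rfree": rec.rfree,
                "phase_error": rec.phase_error,
                "sigma0": rec.sigma0,
                "elite": bool(elite_at is not None and rec.iteration >= elite_at),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_histogram_csv(hist: ReferenceHistogram, path: str | Path) -> None:
    pd.DataFrame({"density": hist.sample}).to_csv(path, index=False)


def read_histogram_csv(path: str | Path) -> ReferenceHistogram:
    df = pd.read_csv(path)
    if "density" not in df.columns:
        raise ValueError(f"{path} lacks a 'density' column")
    return ReferenceHistogram(df["density"].to_numpy())
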