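"""Per-cell and bulk silencing metrics.

For the k-th cell, with M counting spots and I summing integrated spot
intensities (cyto = cytoplasmic, coloc = on-mRNA):

* mRNA stability              ``S(k)     = M_sun_cyto / M_fluc_cyto``
* translational efficiency    ``T_eff(k) = I_sun_coloc_cyto / M_sun_cyto``
* translated fraction         ``T_fra(k) = M_sun_coloc_cyto / M_sun_cyto``
* RISC-binding efficiency     ``A_eff(k) = I_ago_coloc_cyto / M_sun_cyto``
* RISC-positive fraction      ``A_fra(k) = M_ago_coloc_cyto / M_sun_cyto``
* export efficiency           ``E(k)     = M_sun_cyto / M_sun_nuc``

Bulk metrics pool over the included cells as a **ratio of sums** (not the
mean of per-cell ratios): ``S_bulk = ΣM_sun_cyto / ΣM_fluc_cyto`` and
likewise for ``T_eff_bulk`` and ``A_eff_bulk``.  Ribosome numbers per
translated mRNA follow ``R = i_spot / median(free SunTag intensities)`` —
the free-peptide median is the one-peptide calibration unit, so R is a lower
bound (bright spots include nascent partial peptides).

A ratio with zero denominator is NaN (the cell is excluded from that
metric's summaries), never an exception; border-touching cells are excluded
from per-cell metrics altogether.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from silencescope.types import CellGeometry

METRIC_COLUMNS = [
    "cell_id", "M_fluc_cyto", "M_sun_cyto", "M_sun_nuc",
    "M_sun_coloc_cyto", "M_ago_coloc_cyto", "I_sun_coloc_cyto", "I_ago_coloc_cyto",
    "S", "T_eff", "T_fra", "A_eff", "A_fra", "E", "nucleus_area_um2",
]


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def per_cell_metrics(classified: pd.DataFrame,
                     suntag: pd.DataFrame | None = None,
                     ago: pd.DataFrame | None = None,
                     fluc: pd.DataFrame | None = None,
                     geometry: list[CellGeometry] | None = None,
                     include_border: bool = False) -> pd.DataFrame:
    """One row of counts, summed intensities and ratio metrics per cell.

    ``classified`` is the output of
    :func:`~silencescope.colocalize.classify_mrnas`; partner intensities are
    looked up in the ``suntag``/``ago`` spot tables via the matched partner
    ids.  Cells flagged ``touches_border`` are dropped unless
    ``include_border`` is set.
    """
    geoms = {g.cell_id: g for g in (geometry or [])}
    cells = sorted(set(classified.loc[classified["cell_id"] >= 0, "cell_id"]))
    if fluc is not None:
        cells = sorted(set(cells) | set(fluc.loc[fluc["cell_id"] >= 0, "cell_id"]))

    def _intensity_map(table):
        if table is None:
            return {}
        return dict(zip(table["spot_id"], table["integrated_intensity"]))

    sun_int, ago_int = _intensity_map(suntag), _intensity_map(ago)
    rows = []
    for cid in cells:
        if not include_border and cid in geoms and geoms[cid].touches_border:
            continue
        sub = classified[classified["cell_id"] == cid]
        cyto = sub[sub["compartment"] == "cytoplasmic"]
        m_sun_cyto = len(cyto)
        m_sun_nuc = int((sub["compartment"] == "nuclear").sum())
        tr = cyto[cyto["translated"]]
        rp = cyto[cyto["risc_positive"]]
        i_sun = float(sum(sun_int.get(pid, 0.0) for pid in tr["suntag_partner_id"]))
        i_ago = float(sum(ago_int.get(pid, 0.0) for pid in rp["ago_partner_id"]))
        m_fluc = np.nan
        if fluc is not None:
            fsub = fluc[(fluc["cell_id"] == cid) & (fluc["compartment"] == "cytoplasmic")]
            m_fluc = len(fsub)
        rows.append({
            "cell_id": cid,
            "M_fluc_cyto": m_fluc, "M_sun_cyto": m_sun_cyto, "M_sun_nuc": m_sun_nuc,
            "M_sun_coloc_cyto": len(tr) if suntag is not None else np.nan,
            "M_ago_coloc_cyto": len(rp) if ago is not None else np.nan,
            "I_sun_coloc_cyto": i_sun if suntag is not None else np.nan,
            "I_ago_coloc_cyto": i_ago if ago is not None else np.nan,
            "S": float(_safe_div(m_sun_cyto, m_fluc)) if fluc is not None else np.nan,
            "T_eff": float(_safe_div(i_sun, m_sun_cyto)) if suntag is not None else np.nan,
            "T_fra": float(_safe_div(len(tr), m_sun_cyto)) if suntag is not None else np.nan,
            "A_eff": float(_safe_div(i_ago, m_sun_cyto)) if ago is not None else np.nan,
            "A_fra": float(_safe_div(len(rp), m_sun_cyto)) if ago is not None else np.nan,
            "E": float(_safe_div(m_sun_cyto, m_sun_nuc)),
            "nucleus_area_um2": geoms[cid].nucleus_area_um2 if cid in geoms else np.nan,
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def bulk_metrics(cells: pd.DataFrame) -> dict:
    """Pooled ratio-of-sums metrics over the included cell set.

    Raises on an all-zero pooled denominator for a metric whose ingredients
    are present; metrics whose ingredient columns are entirely NaN are
    reported as None.
    """
    if len(cells) == 0:
        raise ValueError("bulk metrics need at least one included cell")
    out: dict = {"n_cells": int(len(cells))}

    def _ratio(name, num_col, den_col):
        num = cells[num_col].astype(float)
        den = cells[den_col].astype(float)
        if den.isna().all() or num.isna().all():
            out[name] = None
            return
        total_den = float(den.sum(skipna=True))
        if total_den == 0:
            raise ValueError(f"pooled denominator {den_col} is zero for {name}")
        out[name] = float(num.sum(skipna=True)) / total_den

    _ratio("S_bulk", "M_sun_cyto", "M_fluc_cyto")
    _ratio("T_eff_bulk", "I_sun_coloc_cyto", "M_sun_cyto")
    _ratio("A_eff_bulk", "I_ago_coloc_cyto", "M_sun_cyto")
    return out


def ribosome_counts(suntag_on_mrna: pd.DataFrame, suntag_free: pd.DataFrame,
                    min_free_per_cell: int = 10) -> pd.DataFrame:
    """Estimated ribosome number per translated mRNA, ``R = i / median(free)``.

    The free-SunTag median is computed per cell when the cell has at least
    ``min_free_per_cell`` cytoplasmic free spots, falling back to the pooled
    population median otherwise.  R is a lower bound on true ribosome number
    (nascent chains carry partial epitope arrays).
    """
    free_cyto = suntag_free[suntag_free["compartment"] == "cytoplasmic"]
    if len(free_cyto) == 0:
        raise ValueError("no free SunTag spots anywhere: cannot calibrate the "
                         "one-peptide intensity unit")
    pooled_median = float(free_cyto["integrated_intensity"].median())
    per_cell_median = free_cyto.groupby("cell_id")["integrated_intensity"].agg(["median", "size"])

    on = suntag_on_mrna[suntag_on_mrna["compartment"] == "cytoplasmic"].copy()
    units = np.full(len(on), pooled_median)
    for i, cid in enumerate(on["cell_id"].to_numpy()):
        if cid in per_cell_median.index and per_cell_median.loc[cid, "size"] >= min_free_per_cell:
            units[i] = per_cell_median.loc[cid, "median"]
    on["R"] = on["integrated_intensity"].to_numpy() / units
    return on[["spot_id", "cell_id", "integrated_intensity", "R"]].reset_index(drop=True)


def loaded_risc_per_cell(ago_copies_per_cell: float, mirna_occupancy: float,
                         sig_figs: int = 1) -> float:
    """Back-of-envelope abundance of RISC loaded with a given miRNA.

    Multiplies the AGO protein copy number per cell by the miRNA's fractional
    occupancy of the loaded pool and rounds to ``sig_figs`` significant
    figures (e.g. ~15,000 AGO copies × 25% miR-21 occupancy → ~4000 loaded
    RISC per cell in U2OS).  This sets the scale against which reporter
    expression must be kept low (≤ ~100 mRNAs/cell) for efficient
    recognition.
    """
    if not 0.0 <= mirna_occupancy <= 1.0:
        raise ValueError("occupancy is a fraction in [0, 1]")
    if ago_copies_per_cell < 0:
        raise ValueError("copy number must be >= 0")
    value = ago_copies_per_cell * mirna_occupancy
    if value == 0:
        return 0.0
    exponent = np.floor(np.log10(abs(value)))
    factor = 10.0 ** (exponent - sig_figs + 1)
    return float(np.round(value / factor) * factor)


def normalize_to_control(cells: pd.DataFrame, control_bulk: dict) -> pd.DataFrame:
    """Add ``S_norm = S / S_bulk(control)``; time-course runs call this with
    the matched time point's negative-control bulk."""
    s_ctrl = control_bulk.get("S_bulk")
    if not s_ctrl:
        raise ValueError("control S_bulk is zero or missing; cannot normalize")
    cells = cells.copy()
    cells["S_norm"] = cells["S"].astype(float) / float(s_ctrl)
    return cells
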