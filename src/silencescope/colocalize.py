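"""Inter-channel drift correction, spot matching, and mRNA classification.

Colocalization is decided in 3D: after subtracting the channel pair's average
drift, an mRNA and a partner spot (SunTag or AGO) are colocalized when their
Euclidean distance is within the gate — 500 nm for mRNA–SunTag, 250 nm for
mRNA–AGO.  The tighter AGO gate limits chance coincidences with the ~2000
free AGO spots per cell.  Matching is greedy one-to-one in ascending distance
order (deterministic; ties broken by lower spot id), so each partner spot
marks at most one mRNA.  Every mRNA is then classified into one of four
classes: RISC-negative/positive × untranslated/translated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SUNTAG_GATE_NM = 500.0
AGO_GATE_NM = 250.0


@dataclass
class DriftVector:
    """Average 3D offset (moving − reference) of one channel pair, in nm."""
    channel_pair: tuple[str, str]
    offset_nm: np.ndarray
    n_pairs_used: int

    def __post_init__(self) -> None:
        self.offset_nm = np.asarray(self.offset_nm, dtype=float)
        if not np.all(np.isfinite(self.offset_nm)):
            raise ValueError("drift offset must be finite")

    @classmethod
    def zero(cls, pair=("ref", "moving")) -> "DriftVector":
        return cls(tuple(pair), np.zeros(3), 0)


def _positions(table: pd.DataFrame) -> np.ndarray:
    return table[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)


def _mutual_nn_offset(ref: np.ndarray, mov: np.ndarray, radius: float):
    tree_ref, tree_mov = cKDTree(ref), cKDTree(mov)
    d_rm, j_rm = tree_mov.query(ref, k=1, distance_upper_bound=radius)
    d_mr, j_mr = tree_ref.query(mov, k=1, distance_upper_bound=radius)
    pairs = []
    for i, (d, j) in enumerate(zip(d_rm, j_rm)):
        if np.isfinite(d) and j < len(mov) and j_mr[j] == i:
            pairs.append((i, j))
    if not pairs:
        return np.zeros(3), 0
    idx = np.asarray(pairs)
    disp = mov[idx[:, 1]] - ref[idx[:, 0]]
    return disp.mean(axis=0), len(pairs)


def estimate_drift(ref: pd.DataFrame, moving: pd.DataFrame,
                   search_radius_nm: float = 500.0, min_pairs: int = 10,
                   refine_radius_nm: float | None = None,
                   channel_pair: tuple[str, str] = ("ref", "moving")) -> DriftVector:
    """Average drift of ``moving`` relative to ``ref`` from mutual nearest
    neighbors within the search radius, with one refinement iteration after
    applying the first-pass offset.

    The refinement pass re-pairs at ``refine_radius_nm`` (default: half the
    search radius) — once the bulk offset is removed, genuine cross-channel
    partners sit within the localization/binding jitter, so the tighter
    radius sheds chance pairs with unrelated spots.  Raises if fewer than
    ``min_pairs`` mutual pairs support the estimate; callers that know the
    drift is zero should pass a zero vector instead.
    """
    if len(ref) == 0 or len(moving) == 0:
        raise ValueError("drift estimation needs nonempty spot tables")
    if refine_radius_nm is None:
        refine_radius_nm = search_radius_nm / 2.0
    rpos, mpos = _positions(ref), _positions(moving)
    offset, n = _mutual_nn_offset(rpos, mpos, search_radius_nm)
    if n >= min_pairs:
        refine, n2 = _mutual_nn_offset(rpos, mpos - offset, refine_radius_nm)
        if n2 >= min_pairs:
            offset, n = offset + refine, n2
    if n < min_pairs:
        raise ValueError(f"only {n} mutual pairs within {search_radius_nm} nm "
                         f"(minimum {min_pairs}); cannot estimate drift")
    return DriftVector(tuple(channel_pair), offset, n)


def match_spots(mrnas: pd.DataFrame, partners: pd.DataFrame, max_dist_nm: float,
                drift: DriftVector | None = None) -> pd.DataFrame:
    """Greedy one-to-one matching of mRNAs to drift-corrected partner spots.

    All candidate pairs within ``max_dist_nm`` (3D Euclidean, after shifting
    partners by −drift) are accepted in ascending distance order, ties broken
    by (mrna id, partner id); each spot joins at most one pair.  Returns a
    DataFrame (mrna_id, partner_id, distance_nm).
    """
    if max_dist_nm < 0:
        raise ValueError("max_dist_nm must be >= 0")
    empty = pd.DataFrame(columns=["mrna_id", "partner_id", "distance_nm"])
    if len(mrnas) == 0 or len(partners) == 0:
        return empty
    mpos = _positions(mrnas)
    ppos = _positions(partners)
    if drift is not None:
        ppos = ppos - drift.offset_nm
    mids = mrnas["spot_id"].to_numpy()
    pids = partners["spot_id"].to_numpy()

    tree = cKDTree(ppos)
    cand = tree.query_ball_point(mpos, r=max_dist_nm)
    rows_i, rows_j = [], []
    for i, js in enumerate(cand):
        rows_i.extend([i] * len(js))
        rows_j.extend(js)
    if not rows_i:
        return empty
    rows_i = np.asarray(rows_i)
    rows_j = np.asarray(rows_j)
    dist = np.linalg.norm(mpos[rows_i] - ppos[rows_j], axis=1)
    order = np.lexsort((pids[rows_j], mids[rows_i], dist))
    used_m: set = set()
    used_p: set = set()
    out = []
    for k in order:
        i, j = rows_i[k], rows_j[k]
        if i in used_m or j in used_p:
            continue
        used_m.add(i)
        used_p.add(j)
        out.append((mids[i], pids[j], dist[k]))
    return pd.DataFrame(out, columns=["mrna_id", "partner_id", "distance_nm"])


def classify_mrnas(mrnas: pd.DataFrame, suntag: pd.DataFrame | None,
                   ago: pd.DataFrame | None,
                   drift_suntag: DriftVector | None = None,
                   drift_ago: DriftVector | None = None,
                   suntag_gate_nm: float = SUNTAG_GATE_NM,
                   ago_gate_nm: float = AGO_GATE_NM) -> pd.DataFrame:
    """Classify every mRNA into the 2×2 (RISC±, translated±) classes.

    Matching runs on cytoplasmic spots only (translation and RISC act in the
    cytoplasm); nuclear mRNAs are retained with both flags False so export
    counting still sees them.  Unassigned spots are ignored.
    """
    mrnas = mrnas[mrnas["compartment"].isin(["nuclear", "cytoplasmic"])]
    cyto = mrnas[mrnas["compartment"] == "cytoplasmic"]

    def _cyto(table):
        if table is None or len(table) == 0:
            return None
        sub = table[table["compartment"] == "cytoplasmic"]
        return sub if len(sub) else None

    out = pd.DataFrame({
        "mrna_spot_id": mrnas["spot_id"].to_numpy(),
        "cell_id": mrnas["cell_id"].to_numpy(),
        "compartment": mrnas["compartment"].to_numpy(),
        "translated": False, "risc_positive": False,
        "suntag_partner_id": -1, "suntag_dist_nm": np.nan,
        "ago_partner_id": -1, "ago_dist_nm": np.nan,
    }).set_index("mrna_spot_id", drop=False)

    sun_c, ago_c = _cyto(suntag), _cyto(ago)
    if sun_c is not None and len(cyto):
        pairs = match_spots(cyto, sun_c, suntag_gate_nm, drift_suntag)
        out.loc[pairs["mrna_id"].to_numpy(), "translated"] = True
        out.loc[pairs["mrna_id"].to_numpy(), "suntag_partner_id"] = pairs["partner_id"].to_numpy()
        out.loc[pairs["mrna_id"].to_numpy(), "suntag_dist_nm"] = pairs["distance_nm"].to_numpy()
    if ago_c is not None and len(cyto):
        pairs = match_spots(cyto, ago_c, ago_gate_nm, drift_ago)
        out.loc[pairs["mrna_id"].to_numpy(), "risc_positive"] = True
        out.loc[pairs["mrna_id"].to_numpy(), "ago_partner_id"] = pairs["partner_id"].to_numpy()
        out.loc[pairs["mrna_id"].to_numpy(), "ago_dist_nm"] = pairs["distance_nm"].to_numpy()

    classes = np.where(out["risc_positive"], "RISC-positive", "RISC-negative")
    classes = np.char.add(classes.astype(str), np.where(out["translated"],
                                                        " translated", " untranslated"))
    out["class_label"] = classes
    return out.reset_index(drop=True)


def partition_free_spots(partners: pd.DataFrame, pairs: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split partner spots into on-mRNA (matched) and free (unmatched) tables;
    the split is disjoint and exhaustive."""
    matched = partners["spot_id"].isin(set(pairs["partner_id"]))
    return partners[matched].copy(), partners[~matched].copy()
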