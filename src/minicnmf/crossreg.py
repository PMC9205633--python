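"""Cross-session registration of cells.

Sessions are aligned by translating a per-session summary image (max
projection of the video, or sum of footprints) to a chosen template session;
cells then match across a session pair when their footprint centroids are
mutual nearest neighbours within a distance threshold.  Pairwise matches are
extended transitively across sessions, and any transitive group whose
members are not all pairwise-matched directly is dissolved back into
singletons — a conservative conflict rule that avoids chaining errors.
"""

from __future__ import annotations

from itertools import combinations
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
import xarray as xr
import networkx as nx

from .motion import match_template_shift, _translate

ABSENT = -1  # master-table marker for "cell not present in this session"


def align_sessions(
    templates: Mapping[Hashable, np.ndarray],
    template_session: Hashable,
    max_shift: int = 20,
) -> dict[Hashable, tuple[int, int]]:
    """Integer (dy, dx) of each session's summary relative to the template's."""
    if template_session not in templates:
        raise KeyError(f"unknown template session {template_session!r}")
    ref = np.asarray(templates[template_session], dtype=float)
    shifts: dict[Hashable, tuple[int, int]] = {}
    for sess, img in templates.items():
        if sess == template_session:
            shifts[sess] = (0, 0)
        else:
            shifts[sess] = match_template_shift(np.asarray(img, dtype=float), ref, max_shift)
    return shifts


def shift_footprints(A: xr.DataArray, shift: tuple[int, int]) -> xr.DataArray:
    """Undo a session shift on every footprint (integer translation)."""
    dy, dx = shift
    if dy == 0 and dx == 0:
        return A
    data = np.stack([_translate(fp, (-dy, -dx)) for fp in A.values])
    return A.copy(data=data)


def calculate_centroids(A: xr.DataArray) -> pd.DataFrame:
    """Intensity-weighted centroid of each footprint -> (unit_id, row, col)."""
    Av = A.values
    weights = Av.reshape(Av.shape[0], -1).sum(axis=1)
    if np.any(weights <= 0):
        raise ValueError("zero footprint: cannot compute centroid")
    rows = np.arange(Av.shape[1])[None, :, None]
    cols = np.arange(Av.shape[2])[None, None, :]
    r = (Av * rows).reshape(Av.shape[0], -1).sum(axis=1) / weights
    c = (Av * cols).reshape(Av.shape[0], -1).sum(axis=1) / weights
    return pd.DataFrame(
        {"unit_id": A.coords["unit"].values, "row": r, "col": c}
    )


def match_centroid_pairs(
    cent_a: pd.DataFrame,
    cent_b: pd.DataFrame,
    param_dist: float = 5.0,
    window: float = 100.0,
) -> pd.DataFrame:
    """Mutual-nearest centroid matches within ``param_dist`` pixels.

    Distances are evaluated inside moving spatial windows of side ``window``
    with 50% overlap (pairs straddling a window boundary are caught by the
    overlap); a pair matches iff each is the other's unique nearest
    neighbour and the distance is within threshold.  Exact distance ties
    discard all tied candidates.
    """
    pa = cent_a[["row", "col"]].to_numpy(dtype=float)
    pb = cent_b[["row", "col"]].to_numpy(dtype=float)
    if len(pa) == 0 or len(pb) == 0:
        return pd.DataFrame(columns=["unit_id_a", "unit_id_b", "distance"])

    lo = np.floor(np.minimum(pa.min(axis=0), pb.min(axis=0)))
    hi = np.ceil(np.maximum(pa.max(axis=0), pb.max(axis=0)))
    step = max(window / 2.0, 1.0)
    dist = np.full((len(pa), len(pb)), np.inf)
    r = lo[0]
    while r <= hi[0]:
        c = lo[1]
        while c <= hi[1]:
            in_a = np.nonzero(
                (pa[:, 0] >= r) & (pa[:, 0] < r + window)
                & (pa[:, 1] >= c) & (pa[:, 1] < c + window)
            )[0]
            in_b = np.nonzero(
                (pb[:, 0] >= r) & (pb[:, 0] < r + window)
                & (pb[:, 1] >= c) & (pb[:, 1] < c + window)
            )[0]
            if len(in_a) and len(in_b):
                d = np.linalg.norm(pa[in_a, None, :] - pb[None, in_b, :], axis=-1)
                dist[np.ix_(in_a, in_b)] = np.minimum(dist[np.ix_(in_a, in_b)], d)
            c += step
        r += step

    rows = []
    for i in range(len(pa)):
        di = dist[i]
        j = int(np.argmin(di))
        if not np.isfinite(di[j]) or di[j] > param_dist:
            continue
        if (di == di[j]).sum() > 1:  # tied nearest in A->B: discard
            continue
        dj = dist[:, j]
        if (dj == dj.min()).sum() > 1 or np.argmin(dj) != i:  # not mutual/unique
            continue
        rows.append(
            {
                "unit_id_a": cent_a["unit_id"].iloc[i],
                "unit_id_b": cent_b["unit_id"].iloc[j],
                "distance": float(di[j]),
            }
        )
    return pd.DataFrame(rows, columns=["unit_id_a", "unit_id_b", "distance"])


def resolve_mappings(
    pairwise: Mapping[tuple[Hashable, Hashable], pd.DataFrame],
    sessions: list[Hashable] | None = None,
) -> pd.DataFrame:
    """Master table from all pairwise matches with transitive conflict removal.

    The union of pairwise matches is grouped transitively; a group survives
    only if every pair of its member sessions is connected by a direct
    pairwise match, otherwise all its members become singletons.  Output has
    one row per putative real cell and one column per session holding that
    session's unit id or the ``ABSENT`` marker.
    """
    if sessions is None:
        sessions = sorted({s for pair in pairwise for s in pair})
    graph = nx.Graph()
    all_cells: set[tuple[Hashable, Hashable]] = set()
    for (sa, sb), table in pairwise.items():
        for _, row in table.iterrows():
            na, nb = (sa, row["unit_id_a"]), (sb, row["unit_id_b"])
            graph.add_edge(na, nb)
            all_cells.update((na, nb))

    rows = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp, key=lambda n: (sessions.index(n[0]), n[1]))
        by_session: dict[Hashable, list] = {}
        for sess, uid in comp:
            by_session.setdefault(sess, []).append(uid)
        consistent = all(len(v) == 1 for v in by_session.values())
        if consistent:
            for sa, sb in combinations(sorted(by_session, key=sessions.index), 2):
                ua, ub = by_session[sa][0], by_session[sb][0]
                direct = graph.has_edge((sa, ua), (sb, ub))
                if not direct:
                    consistent = False
                    break
        if consistent:
            rows.append({sess: by_session[sess][0] for sess in by_session})
        else:  # dissolve the whole group into singletons
            rows.extend({sess: uid} for sess, uid in comp)

    master = pd.DataFrame(rows, columns=sessions)
    master = master.fillna(ABSENT)
    for sess in sessions:
        if master[sess].dtype != object:
            master[sess] = master[sess].astype(int)
    return master.reset_index(drop=True)


def cross_register(
    footprints: Mapping[Hashable, xr.DataArray],
    templates: Mapping[Hashable, np.ndarray] | None = None,
    template_session: Hashable | None = None,
    param_dist: float = 5.0,
    window: float = 100.0,
    max_shift: int = 20,
) -> tuple[pd.DataFrame, dict[tuple[Hashable, Hashable], pd.DataFrame]]:
    """Full cross-registration: align, centroid-match all pairs, resolve.

    ``templates`` defaults to the summed footprint projection per session.
    """
    sessions = list(footprints)
    if templates is None:
        templates = {s: footprints[s].values.sum(axis=0) for s in sessions}
    if template_session is None:
        template_session = sessions[0]
    shifts = align_sessions(templates, template_session, max_shift=max_shift)
    centroids = {
        s: calculate_centroids(shift_footprints(footprints[s], shifts[s]))
        for s in sessions
    }
    pairwise = {
        (sa, sb): match_centroid_pairs(
            centroids[sa], centroids[sb], param_dist=param_dist, window=window
        )
        for sa, sb in combinations(sessions, 2)
    }
    return resolve_mappings(pairwise, sessions), pairwise
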