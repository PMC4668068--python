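"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-pixel scans, BFS flood fill) and
shares no code with the package internals it validates.
"""

from collections import deque

import numpy as np

NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_components(mask):
    """All 8-connected components of a binary mask, as lists of pixel sets."""
    mask = np.asarray(mask)
    n_rows, n_cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(n_rows):
        for c in range(n_cols):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    rr, cc = q.popleft()
                    comp.add((rr, cc))
                    for dr, dc in NEIGHBOURS_8:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < n_rows and 0 <= c2 < n_cols and mask[r2, c2] and not seen[r2, c2]:
                            seen[r2, c2] = True
                            q.append((r2, c2))
                comps.append(comp)
    return comps


def is_8_connected(pixels):
    """True if a pixel set is a single 8-connected component."""
    pixels = set(pixels)
    if not pixels:
        return False
    start = next(iter(pixels))
    seen = {start}
    q = deque([start])
    while q:
        r, c = q.popleft()
        for dr, dc in NEIGHBOURS_8:
            p = (r + dr, c + dc)
            if p in pixels and p not in seen:
                seen.add(p)
                q.append(p)
    return seen == pixels


def per_pixel_annual_frequency(history, unit_mask, window_years):
    """Mean fires/year by per-pixel counting: burnt-year count / window length,
    averaged over unit pixels."""
    idxs = [history.year_index(y) for y in window_years]
    annual = np.logical_or(history.eds[idxs], history.lds[idxs])
    counts = annual.sum(axis=0)  # burnt years per pixel
    return counts[unit_mask].mean() / len(window_years)


def per_pixel_unburnt_proportion(history, unit_mask, as_of_year, min_years):
    """Fraction of unit pixels with no burn in the last min_years calendar years."""
    years = range(as_of_year - min_years + 1, as_of_year + 1)
    burnt = np.zeros(history.grid.shape, dtype=bool)
    for y in years:
        i = history.year_index(y)
        burnt |= history.eds[i].astype(bool) | history.lds[i].astype(bool)
    return (~burnt)[unit_mask].mean()


def per_pixel_tslb(history, as_of_year):
    """Per-pixel whole-years-since-last-burn by backwards scan; None = never."""
    out = {}
    for r in range(history.grid.n_rows):
        for c in range(history.grid.n_cols):
            tslb = None
            for y in range(as_of_year, history.years[0] - 1, -1):
                i = history.year_index(y)
                if history.eds[i, r, c] or history.lds[i, r, c]:
                    tslb = as_of_year - y
                    break
            out[(r, c)] = tslb
    return out
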