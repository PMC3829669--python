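"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

from typing import List, Set, Tuple

import numpy as np


def flood_fill_components(mask: np.ndarray) -> List[Set[Tuple[int, int]]]:
    """All 8-connected components of a boolean mask by explicit BFS.

    Deliberately naive: no labelling library, no recursion tricks. Used as
    the independent reference for connected-component extraction.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps: List[Set[Tuple[int, int]]] = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


def ols_normal_equations(x, y) -> Tuple[float, float, float]:
    """Least-squares line + R^2 straight from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = ((y - slope * x - intercept) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)
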