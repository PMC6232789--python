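"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (flood fill, grid search, closed forms)
and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a binary raster by breadth-first flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    components = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        queue = [start]
        visited[start] = True
        comp = set()
        while queue:
            r, c = queue.pop()
            comp.add((r, c))
            for dr, dc in steps:
                nr, nc = r + dr, c + dc
                if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                        and mask[nr, nc] and not visited[nr, nc]):
                    visited[nr, nc] = True
                    queue.append((nr, nc))
        components.append(frozenset(comp))
    return components


def grid_search_monoexp(
    te_ms: np.ndarray,
    signal: np.ndarray,
    rate_max: float = 0.5,
    n_coarse: int = 400,
    n_fine: int = 400,
) -> tuple[float, float, float]:
    """Brute-force (S0, rate) fit of S = S0 exp(-rate te) by profiled grid search.

    For each candidate rate (per ms), the optimal amplitude has the closed
    form S0*(rate) = sum(S e) / sum(e^2) with e = exp(-rate te); the grid is
    scanned coarsely over [0, rate_max] and refined once around the best
    point.  Returns (rate per ms, amplitude, rss).
    """
    te_ms = np.asarray(te_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)

    def profile(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = np.exp(-np.outer(rates, te_ms))  # (n_rates, n_te)
        denom = np.sum(e * e, axis=1)
        amp = np.sum(e * signal, axis=1) / denom
        rss = np.sum((signal - amp[:, None] * e) ** 2, axis=1)
        return amp, rss

    coarse = np.linspace(0.0, rate_max, n_coarse)
    amp_c, rss_c = profile(coarse)
    i = int(np.argmin(rss_c))
    lo = coarse[max(0, i - 1)]
    hi = coarse[min(n_coarse - 1, i + 1)]
    fine = np.linspace(lo, hi, n_fine)
    amp_f, rss_f = profile(fine)
    j = int(np.argmin(rss_f))
    return float(fine[j]), float(amp_f[j]), float(rss_f[j])


def pooled_t_closed_form(a, b) -> tuple[float, float, int]:
    """Textbook pooled-variance two-sample t statistic and two-tailed p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def normal_equations_line(x, y) -> tuple[float, float]:
    """OLS slope/intercept from the 2x2 normal equations, solved directly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    a = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    rhs = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(a, rhs)
    return float(slope), float(intercept)
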