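"""Geographic distances, isolation by distance and geographic clines.

Two distance modes are supported.  *Straight-line* distances are
great-circle (haversine) kilometres on a sphere of radius 6371.0088 km
(the IUGG mean).  *Ring* distances respect a habitat ring around an
uninhabitable interior: within-arc pairs keep their great-circle
distance, while a pair spanning the two arcs is routed through a single
reference point on the far side of the ring, ``d(w, ref) + d(ref, e)``.

Clines along the ring use the standard sigmoid
``Phi(x) = (1 + tanh(2 (x - c) / w)) / 2`` with centre ``c`` (position of
steepest change) and width ``w`` (inverse of the maximum slope), scaled
to observed trait extremes, with optional exponential tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ARC_REFERENCE, SiteTable

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(a, b, radius: float = EARTH_RADIUS_KM) -> float:
    """Haversine distance in km between (lon, lat) points in degrees."""
    lon1, lat1 = np.radians(np.asarray(a, dtype=float))
    lon2, lat2 = np.radians(np.asarray(b, dtype=float))
    if not (abs(np.degrees(lat1)) <= 90 and abs(np.degrees(lat2)) <= 90):
        raise ValueError("latitude out of range")
    h = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return float(2.0 * radius * np.arcsin(np.sqrt(h)))


@dataclass
class DistanceMatrix:
    values: pd.DataFrame
    mode: str = "straight"

    @property
    def codes(self) -> list:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def straight_distance_matrix(sites: SiteTable) -> DistanceMatrix:
    """Great-circle distances among the sampled sites."""
    s = sites.sampled()
    codes = s.codes
    m = np.zeros((len(codes), len(codes)))
    for i, a in enumerate(codes):
        for j in range(i + 1, len(codes)):
            d = great_circle_km(s.coords(a), s.coords(codes[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(pd.DataFrame(m, index=codes, columns=codes),
                          mode="straight")


def ring_distance_matrix(sites: SiteTable) -> DistanceMatrix:
    """Ring distances: cross-arc pairs routed through the reference point."""
    ref = sites.reference_code()
    ref_xy = sites.coords(ref)
    s = sites.sampled()
    codes = s.codes
    arcs = {c: s.arc_of(c) for c in codes}
    m = np.zeros((len(codes), len(codes)))
    for i, a in enumerate(codes):
        for j in range(i + 1, len(codes)):
            b = codes[j]
            if arcs[a] != arcs[b]:
                d = (great_circle_km(s.coords(a), ref_xy)
                     + great_circle_km(ref_xy, s.coords(b)))
            else:
                d = great_circle_km(s.coords(a), s.coords(b))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(pd.DataFrame(m, index=codes, columns=codes),
                          mode="ring")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(genetic, geographic, n_perm: int = 1000,
                seed: int | None = None) -> tuple:
    """Mantel correlation between two square matrices with permutation p.

    ``r`` is the Pearson correlation over lower-triangle entries; the
    p-value co-permutes rows and columns of the genetic matrix,
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)``.  Matrices must share
    the same site order.
    """
    G = genetic.values.to_numpy() if hasattr(genetic, "values") and \
        isinstance(getattr(genetic, "values"), pd.DataFrame) else np.asarray(
            getattr(genetic, "values", genetic), dtype=float)
    D = geographic.values.to_numpy() if isinstance(
        geographic, DistanceMatrix) else np.asarray(
            getattr(geographic, "values", geographic), dtype=float)
    if G.shape != D.shape or G.shape[0] != G.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = G.shape[0]
    il = np.tril_indices(n, -1)
    g, d = G[il], D[il]
    if np.std(g) == 0 or np.std(d) == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    r_obs = float(np.corrcoef(g, d)[0, 1])
    if n_perm <= 0:
        return r_obs, np.nan
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = G[np.ix_(perm, perm)][il]
        if np.corrcoef(gp, d)[0, 1] >= r_obs:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# ring positions
# ---------------------------------------------------------------------------

def ring_positions(sites: SiteTable, origin: str = "QCS",
                   gap_between: tuple | None = None) -> pd.Series:
    """1-D positions (km) of sampled sites along the ring from ``origin``.

    Sites are ordered by angle around their centroid; the ring's gap is
    the largest angular gap between consecutive sites (or the pair named
    by ``gap_between``), and the chain runs away from the gap.  ``origin``
    must be one of the two chain ends, otherwise the ordering is
    ambiguous and an error is raised.  Positions are cumulative
    great-circle distances between consecutive sites.
    """
    s = sites.sampled()
    codes = s.codes
    if len(codes) < 3:
        raise ValueError("ring ordering needs at least 3 sites")
    if origin not in codes:
        raise ValueError(f"origin {origin!r} not among sites")
    lon = s.table["lon"].to_numpy()
    lat = s.table["lat"].to_numpy()

    def angle(lons, lats):
        return np.arctan2(lats - lat.mean(),
                          (lons - lon.mean()) * np.cos(np.radians(lat.mean())))

    ang = angle(lon, lat)
    order = np.argsort(ang)
    sorted_codes = [codes[i] for i in order]
    gaps = np.diff(np.r_[ang[order], ang[order][0] + 2 * np.pi])
    if gap_between is not None:
        a, b = gap_between
        try:
            ia = sorted_codes.index(a)
        except ValueError:
            raise ValueError(f"gap site {a!r} not among sites") from None
        if sorted_codes[(ia + 1) % len(codes)] == b:
            cut = ia
        elif sorted_codes[ia - 1] == b:
            cut = (ia - 1) % len(codes)
        else:
            raise ValueError(
                f"gap sites {a!r}, {b!r} are not angularly adjacent")
    else:
        try:
            ref = sites.reference_code()
        except ValueError:
            ref = None
        if ref is not None:
            # the reference sits on the ring opposite the gap, so the
            # gap is the inter-site interval containing its antipode
            rlon, rlat = sites.coords(ref)
            ref_ang = float(angle(np.asarray(rlon), np.asarray(rlat)))
            target = (ref_ang + np.pi) % (2 * np.pi)
            starts = ang[order] % (2 * np.pi)
            offset = (target - starts) % (2 * np.pi)
            cut = int(np.argmin(np.where(offset <= gaps, offset, np.inf)))
        else:
            cut = int(np.argmax(gaps))
    chain = sorted_codes[cut + 1:] + sorted_codes[:cut + 1]
    if chain[-1] == origin:
        chain = chain[::-1]
    elif chain[0] != origin:
        raise ValueError(
            f"ambiguous ordering: origin {origin!r} is interior to the "
            f"chain {chain}; it must flank the gap")
    pos = [0.0]
    for a, b in zip(chain, chain[1:]):
        pos.append(pos[-1] + great_circle_km(s.coords(a), s.coords(b)))
    return pd.Series(pos, index=chain, name="ring_position_km")


# ---------------------------------------------------------------------------
# clines
# ---------------------------------------------------------------------------

def _sigmoid(x, c, w):
    return 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))


def _sigmoid_deriv(x, c, w):
    return (1.0 - np.tanh(2.0 * (x - c) / w) ** 2) / w


def cline_value(x, c, w, p_min, p_max, tails: str = "none",
                delta_l: float = 0.0, tau_l: float = 1.0,
                delta_r: float = 0.0, tau_r: float = 1.0,
                ascending: bool = True):
    """Expected trait on the cline at position(s) ``x``.

    The centre sigmoid has unit range; tails replace it beyond a distance
    ``delta`` from the centre by an exponential approach to the asymptote
    whose log-slope at the joint is ``tau`` times the sigmoid's (``tau`` =
    1 keeps the profile smooth; smaller values flatten the tail).
    ``tails`` is one of none/left/right/mirror/both; ``mirror`` shares one
    (delta, tau) pair on both sides.  The result is scaled to
    ``[p_min, p_max]``, increasing with ``x`` unless ``ascending`` is
    False.
    """
    if w <= 0:
        raise ValueError("width must be positive")
    if tails not in ("none", "left", "right", "mirror", "both"):
        raise ValueError(f"unknown tail variant {tails!r}")
    x = np.asarray(x, dtype=float)
    y = _sigmoid(x, c, w)
    if tails == "mirror":
        delta_r, tau_r = delta_l, tau_l
    fit_left = tails in ("left", "mirror", "both")
    fit_right = tails in ("right", "mirror", "both")
    if fit_left:
        xl = c - delta_l
        yl = _sigmoid(xl, c, w)
        if yl > 0:  # at yl == 0 the sigmoid already sits on the asymptote
            sl = tau_l * _sigmoid_deriv(xl, c, w) / yl
            left = x < xl
            expo = np.clip(sl * (x - xl), -700.0, 0.0)
            y = np.where(left, yl * np.exp(expo), y)
    if fit_right:
        xr = c + delta_r
        yr = _sigmoid(xr, c, w)
        if yr < 1:
            sr = tau_r * _sigmoid_deriv(xr, c, w) / (1.0 - yr)
            right = x > xr
            expo = np.clip(-sr * (x - xr), -700.0, 0.0)
            y = np.where(right, 1.0 - (1.0 - yr) * np.exp(expo), y)
    if not ascending:
        y = 1.0 - y
    out = p_min + (p_max - p_min) * y
    return float(out) if out.ndim == 0 else out


#: free parameters (beyond the error variance) per tail variant
_VARIANT_PARAMS = {
    "null": [],
    "none": ["c", "w"],
    "left": ["c", "w", "delta_l", "tau_l"],
    "right": ["c", "w", "delta_r", "tau_r"],
    "mirror": ["c", "w", "delta_l", "tau_l"],
    "both": ["c", "w", "delta_l", "tau_l", "delta_r", "tau_r"],
}

#: AIC parameter counts, including the error variance (null: mean + var)
VARIANT_K = {"null": 2, "none": 3, "left": 5, "right": 5, "mirror": 5,
             "both": 7}


@dataclass
class ClineFit:
    variant: str
    center: float
    width: float
    p_min: float
    p_max: float
    tail_params: dict
    ascending: bool
    log_likelihood: float
    aic: float
    support_center: tuple = field(default=(np.nan, np.nan))
    support_width: tuple = field(default=(np.nan, np.nan))

    def predict(self, x):
        if self.variant == "null":
            return np.full_like(np.asarray(x, dtype=float),
                                (self.p_min + self.p_max) / 2.0)
        return cline_value(x, self.center, self.width, self.p_min,
                           self.p_max, tails=self.variant,
                           ascending=self.ascending, **self.tail_params)


def _gauss_lnl(resid: np.ndarray) -> float:
    n = resid.size
    sse = float((resid ** 2).sum())
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_cline(positions, traits, variants=("null", "none", "left", "right",
                                           "mirror", "both"),
              n_starts: int = 8, seed: int | None = None,
              extreme_quantile: float | None = None) -> tuple:
    """Maximum-likelihood cline fits with AIC model comparison.

    ``positions`` and ``traits`` are matched 1-D arrays (>= 4 sites).
    Trait extremes fix ``p_min``/``p_max``: the raw observed min/max by
    default, or — when ``extreme_quantile`` is given (e.g. 0.1) — the
    means of the traits beyond that lower/upper quantile, a noise-robust
    version of "fixed to observed" (raw extremes inflate the amplitude,
    and hence the fitted width, when site noise is appreciable).  Each
    tail variant is fit by Gaussian ML from ``n_starts`` random
    initialisations, in both ascending and descending orientation.
    Returns ``(best, table)``: the best :class:`ClineFit` by AIC and a
    per-variant DataFrame.  2-unit log-likelihood support ranges for
    centre and width are profiled on a grid with the other parameters
    held at their estimates.
    """
    x = np.asarray(positions, dtype=float)
    yv = np.asarray(traits, dtype=float)
    if x.size < 4:
        raise ValueError("cline fitting needs >= 4 sites")
    if not np.isfinite(yv).all():
        raise ValueError("traits must be finite")
    if extreme_quantile is None:
        p_min, p_max = float(yv.min()), float(yv.max())
    else:
        if not 0 < extreme_quantile < 0.5:
            raise ValueError("extreme_quantile must be in (0, 0.5)")
        lo_q, hi_q = np.quantile(yv, [extreme_quantile, 1 - extreme_quantile])
        p_min = float(yv[yv <= lo_q].mean())
        p_max = float(yv[yv >= hi_q].mean())
    span = float(x.max() - x.min()) or 1.0
    rng = np.random.default_rng(seed)
    fits = []
    for variant in variants:
        if variant == "null":
            resid = yv - (p_min + p_max) / 2.0
            lnl = _gauss_lnl(resid)
            fits.append(ClineFit(variant, np.nan, np.nan, p_min, p_max, {},
                                 True, lnl, 2 * VARIANT_K[variant] - 2 * lnl))
            continue
        names = _VARIANT_PARAMS[variant]
        lo = {"c": x.min() - span, "w": 1e-3 * span, "delta_l": 0.0,
              "tau_l": 1e-3, "delta_r": 0.0, "tau_r": 1e-3}
        hi = {"c": x.max() + span, "w": 4.0 * span, "delta_l": span,
              "tau_l": 1.0, "delta_r": span, "tau_r": 1.0}

        def unpack(theta):
            out = dict(zip(names, theta))
            tail = {k: v for k, v in out.items() if k.startswith(("delta",
                                                                  "tau"))}
            return out["c"], out["w"], tail

        best = None
        for ascending in (True, False):
            def sse(theta, asc=ascending):
                c, w, tail = unpack(theta)
                if w <= 0:
                    return 1e12
                pred = cline_value(x, c, w, p_min, p_max, tails=variant,
                                   ascending=asc, **tail)
                return float(((yv - pred) ** 2).sum())

            for _ in range(n_starts):
                theta0 = [rng.uniform(lo[n_], hi[n_]) for n_ in names]
                res = optimize.minimize(
                    sse, theta0, method="Nelder-Mead",
                    options={"maxiter": 400 * len(names), "xatol": 1e-4,
                             "fatol": 1e-10})
                cand = (res.fun, res.x, ascending)
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is None:
            raise RuntimeError(f"no convergence for variant {variant!r}")
        sse_best, theta, ascending = best
        c, w, tail = unpack(theta)
        w = abs(w)
        resid = yv - cline_value(x, c, w, p_min, p_max, tails=variant,
                                 ascending=ascending, **tail)
        lnl = _gauss_lnl(resid)
        fit = ClineFit(variant, float(c), float(w), p_min, p_max, tail,
                       ascending, lnl, 2 * VARIANT_K[variant] - 2 * lnl)
        fit.support_center = _support_interval(
            lambda cc: _gauss_lnl(yv - cline_value(
                x, cc, w, p_min, p_max, tails=variant, ascending=ascending,
                **tail)),
            c, lnl, lo["c"], hi["c"])
        fit.support_width = _support_interval(
            lambda ww: _gauss_lnl(yv - cline_value(
                x, c, max(ww, 1e-9), p_min, p_max, tails=variant,
                ascending=ascending, **tail)),
            w, lnl, lo["w"], hi["w"])
        fits.append(fit)
    table = pd.DataFrame(
        [{"variant": f.variant, "center": f.center, "width": f.width,
          "lnL": f.log_likelihood, "k": VARIANT_K[f.variant], "AIC": f.aic}
         for f in fits]).sort_values("AIC").reset_index(drop=True)
    best_fit = min(fits, key=lambda f: f.aic)
    return best_fit, table


def _support_interval(lnl_of, mle: float, lnl_max: float, lo: float,
                      hi: float, drop: float = 2.0) -> tuple:
    """Range of values whose log-likelihood is within ``drop`` of the max
    (other parameters held fixed at their estimates); the crossing on
    each side is located by bisection."""
    threshold = lnl_max - drop

    def crossing(inside: float, outside: float) -> float:
        if lnl_of(outside) >= threshold:
            return outside
        for _ in range(60):
            mid = 0.5 * (inside + outside)
            if lnl_of(mid) >= threshold:
                inside = mid
            else:
                outside = mid
            if abs(outside - inside) < 1e-9 * max(1.0, abs(mle)):
                break
        return inside

    return (crossing(mle, lo), crossing(mle, hi))


def diversity_along_ring(div_table: pd.DataFrame, positions: pd.Series,
                         sites: SiteTable | None = None,
                         value_cols=("pct_polymorphic", "pi_rad")) -> tuple:
    """Diversity profile ordered by ring position, with trend tests.

    Returns ``(profile, trends)``: the diversity rows reindexed in ring
    order with a ``ring_position_km`` column, and Spearman trend tests of
    each value column against position — overall and per arc when a site
    table is supplied.  Populations without a ring position are dropped
    with their absence reflected in the profile.
    """
    shared = [c for c in positions.index if c in div_table.index]
    profile = div_table.loc[shared, list(value_cols)].copy()
    profile.insert(0, "ring_position_km", positions.loc[shared])
    profile = profile.sort_values("ring_position_km")
    trends = {}
    subsets = {"all": list(profile.index)}
    if sites is not None:
        for arc in ("west", "east"):
            subsets[arc] = [c for c in profile.index
                            if sites.arc_of(c) == arc]
    for label, codes in subsets.items():
        if len(codes) < 3:
            continue
        for col in value_cols:
            rho, p = stats.spearmanr(profile.loc[codes, "ring_position_km"],
                                     profile.loc[codes, col])
            trends[(label, col)] = {"rho": float(rho), "p": float(p)}
    return profile, trends
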