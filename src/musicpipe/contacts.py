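"""Binned contact maps, distance-decay curves and compartment scores.

Distance decay comes in two flavours: the high-resolution P_c(s) curve
(500,000 equal-width bins spanning 10 bp to 150 Mb) and the per-cell
log-binned profile (150 log2-spaced bins from 5 kb to 150 Mb, each bin
frequency normalised by bin width and then to unit mass per cell) that
the LCS-erosion score is read from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import WeightedContact

PC_S_MIN = 10.0
PC_S_MAX = 1.5e8
PC_N_BINS = 500_000

LOGBIN_MIN = 5_000.0
LOGBIN_MAX = 1.5e8
LOGBIN_N = 150


def logbin_edges(n_bins: int = LOGBIN_N) -> np.ndarray:
    """Log2-spaced bin edges: 2**(log2(5000) + step*n), n = 0..n_bins."""
    step = (np.log2(LOGBIN_MAX) - np.log2(LOGBIN_MIN)) / n_bins
    return 2.0 ** (np.log2(LOGBIN_MIN) + step * np.arange(n_bins + 1))


# ------------------------------------------------------------- 2D matrices

@dataclass
class BinScheme:
    """Fixed-width binning of one chromosome (or a region of it)."""

    chrom: str
    resolution: int
    start: int = 0
    end: int | None = None  # half-open; None = use max seen + resolution

    def bin_of(self, pos: int) -> int | None:
        if pos < self.start or (self.end is not None and pos >= self.end):
            return None
        return (pos - self.start) // self.resolution

    @property
    def n_bins(self) -> int:
        if self.end is None:
            raise ValueError("open-ended scheme has no fixed bin count")
        return -(-(self.end - self.start) // self.resolution)


@dataclass
class ContactMatrix:
    scheme: BinScheme
    weights: dict[tuple[int, int], float] = field(default_factory=dict)
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def add(self, i: int, j: int, w: float) -> None:
        key = (i, j) if i <= j else (j, i)
        self.weights[key] = self.weights.get(key, 0.0) + w

    @property
    def total(self) -> float:
        return sum(self.weights.values())

    def dense(self) -> np.ndarray:
        n = self.scheme.n_bins
        m = np.zeros((n, n))
        for (i, j), w in self.weights.items():
            m[i, j] += w
            if i != j:
                m[j, i] += w
        return m

    def write_triplets(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_i\tbin_j\tweight\n")
            for (i, j), w in sorted(self.weights.items()):
                fh.write(f"{i}\t{j}\t{w:.6g}\n")


def contact_matrix(
    contacts: list[WeightedContact],
    scheme: BinScheme,
    size_class: tuple[int, int] | None = None,
) -> ContactMatrix:
    """Weighted upper-triangular binning of pairwise contacts.

    ``size_class`` restricts to contacts whose (region-restricted)
    cluster size lies in the inclusive range — the small (2-10),
    middle (11-50) and large (51-100) cluster classes.  Contacts with
    either end outside the scheme are dropped and counted.
    """
    m = ContactMatrix(scheme=scheme, meta={"size_class": size_class})
    for c in contacts:
        if size_class is not None and not (size_class[0] <= c.cluster_size <= size_class[1]):
            continue
        if c.a.chrom != scheme.chrom or c.b.chrom != scheme.chrom:
            m.n_dropped += 1
            continue
        i, j = scheme.bin_of(c.a.pos), scheme.bin_of(c.b.pos)
        if i is None or j is None:
            m.n_dropped += 1
            continue
        m.add(i, j, c.weight)
    return m


def visual_transform(m: np.ndarray, factor: int = 100) -> np.ndarray:
    """Entrywise log10(1 + factor*w): linear scale-up then log transform."""
    return np.log10(1.0 + factor * np.asarray(m, dtype=float))


def normalize_map_pair(
    a: np.ndarray, b: np.ndarray, factor: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Log-scale two maps and normalise each to its own maximum.

    Output entries lie in [0, 1] with max exactly 1 unless a map is
    all-zero (returned all-zero, with a warning).
    """
    import warnings

    out = []
    for m in (a, b):
        t = visual_transform(m, factor)
        mx = t.max() if t.size else 0.0
        if mx <= 0:
            warnings.warn("all-zero contact map; normalisation skipped")
            out.append(t)
        else:
            out.append(t / mx)
    return out[0], out[1]


# --------------------------------------------------------------- P_c(s)

@dataclass
class PcCurve:
    edges: np.ndarray      # len n_bins + 1, linear
    freq: np.ndarray       # len n_bins, weight mass per bin
    n_excluded: int = 0    # pairs outside the distance range
    n_cells: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _intra_distances(
    contacts: list[WeightedContact],
    arms: dict[str, int] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """(distance, weight, cell index arrays, n_excluded) for DNA-DNA pairs.

    Interchromosomal pairs are ignored; with an arm table, pairs whose
    ends straddle the arm boundary are excluded and counted.
    """
    cells: dict[str, int] = {}
    d, w, ci = [], [], []
    excluded = 0
    for c in contacts:
        if c.a.chrom != c.b.chrom:
            continue
        if arms is not None:
            boundary = arms.get(c.a.chrom)
            if boundary is not None and (c.a.pos < boundary) != (c.b.pos < boundary):
                excluded += 1
                continue
        d.append(abs(c.a.pos - c.b.pos))
        w.append(c.weight)
        ci.append(cells.setdefault(c.cell_id, len(cells)))
    return np.asarray(d, float), np.asarray(w, float), np.asarray(ci), excluded


def pc_curve(
    contacts: list[WeightedContact],
    arms: dict[str, int] | None = None,
    n_bins: int = PC_N_BINS,
    s_range: tuple[float, float] = (PC_S_MIN, PC_S_MAX),
    mode: str = "per_cell_then_sum",
) -> PcCurve:
    """Contact frequency versus genomic distance.

    The distance range is divided into ``n_bins`` equal-width bins and
    pair weights are summed per bin.  ``per_cell_then_sum`` normalises
    each cell's curve to unit mass before aggregating (the single-cell
    convention); ``pool_all`` histograms all pairs at once.
    """
    if mode not in ("per_cell_then_sum", "pool_all"):
        raise ValueError(f"unknown mode {mode!r}")
    edges = np.linspace(s_range[0], s_range[1], n_bins + 1)
    d, w, ci, excluded = _intra_distances(contacts, arms)
    in_range = (d >= s_range[0]) & (d <= s_range[1])
    excluded += int((~in_range).sum())
    d, w, ci = d[in_range], w[in_range], ci[in_range]
    n_cells = len(np.unique(ci)) if len(ci) else 0

    if mode == "pool_all":
        freq, _ = np.histogram(d, bins=edges, weights=w)
    else:
        freq = np.zeros(n_bins)
        for cell in np.unique(ci):
            sel = ci == cell
            h, _ = np.histogram(d[sel], bins=edges, weights=w[sel])
            total = h.sum()
            if total > 0:
                freq += h / total
    return PcCurve(edges=edges, freq=freq, n_excluded=excluded, n_cells=n_cells)


def pc_curve_from_distances(
    distances: np.ndarray,
    weights: np.ndarray | None = None,
    n_bins: int = PC_N_BINS,
    s_range: tuple[float, float] = (PC_S_MIN, PC_S_MAX),
) -> PcCurve:
    """Pooled P_c(s) directly from a distance sample."""
    edges = np.linspace(s_range[0], s_range[1], n_bins + 1)
    freq, _ = np.histogram(distances, bins=edges, weights=weights)
    n_exc = len(distances) - int(
        ((distances >= s_range[0]) & (distances <= s_range[1])).sum()
    )
    return PcCurve(edges=edges, freq=freq, n_excluded=n_exc, n_cells=1)


def fit_decay_exponent(
    curve: PcCurve,
    s_range: tuple[float, float] | None = None,
    n_logbins: int = 50,
) -> float:
    """Log-log slope of the decay curve (the exponent is -slope).

    The linear-bin curve is re-aggregated into log-spaced bins, each
    bin's mass converted to a density by its width, and a least-squares
    line fitted to log10(density) vs log10(distance) over non-empty
    bins.
    """
    lo = s_range[0] if s_range else max(curve.edges[0], 1.0)
    hi = s_range[1] if s_range else curve.edges[-1]
    log_edges = np.logspace(np.log10(lo), np.log10(hi), n_logbins + 1)
    centers = curve.centers
    mass, _ = np.histogram(centers, bins=log_edges, weights=curve.freq)
    widths = np.diff(log_edges)
    mids = np.sqrt(log_edges[:-1] * log_edges[1:])
    ok = mass > 0
    x = np.log10(mids[ok])
    y = np.log10(mass[ok] / widths[ok])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


# ------------------------------------------------------- log-bin profiles

@dataclass
class LogBinProfile:
    edges: np.ndarray   # LOGBIN_N + 1 log2-spaced edges
    values: np.ndarray  # LOGBIN_N, width-normalised, unit total mass
    n_nonempty: int = 0

    @property
    def midpoints(self) -> np.ndarray:
        """Geometric-mean bin midpoints (natural for log-spaced bins)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])


def logbin_profile(
    distances: np.ndarray, weights: np.ndarray | None = None
) -> LogBinProfile:
    """Per-cell log-binned distance profile.

    Pair mass is histogrammed over the 150 log2-spaced bins, divided by
    bin width, and normalised to total 1 (for any cell with at least
    one in-range contact).
    """
    edges = logbin_edges()
    mass, _ = np.histogram(distances, bins=edges, weights=weights)
    dens = mass / np.diff(edges)
    total = dens.sum()
    if total > 0:
        dens = dens / total
    return LogBinProfile(edges=edges, values=dens, n_nonempty=int((mass > 0).sum()))


def logbin_profile_from_contacts(
    contacts: list[WeightedContact], arms: dict[str, int] | None = None
) -> LogBinProfile:
    d, w, _, _ = _intra_distances(contacts, arms)
    return logbin_profile(d, w)


# ------------------------------------------------------- compartments

def expected_by_distance(m: np.ndarray) -> np.ndarray:
    """Distance-stratified mean: expected[i, j] = mean over |i-j|."""
    n = m.shape[0]
    exp = np.zeros_like(m, dtype=float)
    for k in range(n):
        diag = np.diagonal(m, k)
        mu = diag.mean() if diag.size else 0.0
        idx = np.arange(n - k)
        exp[idx, idx + k] = mu
        exp[idx + k, idx] = mu
    return exp


def compartment_track(
    m: np.ndarray,
    reference: np.ndarray | None = None,
    min_informative_bins: int = 10,
) -> np.ndarray:
    """PC1 of the correlation matrix of the observed/expected map.

    The expected map is the distance-stratified mean; bins with no
    signal are masked (NaN in the output).  The eigenvector sign is
    arbitrary, so it is oriented to correlate positively with
    ``reference`` when one is given (e.g. a gene-density track).
    Raises ``ValueError`` on degenerate input.
    """
    m = np.asarray(m, dtype=float)
    informative = m.sum(axis=0) > 0
    if informative.sum() < min_informative_bins:
        raise ValueError("fewer than 10 informative bins")
    sub = m[np.ix_(informative, informative)]
    exp = expected_by_distance(sub)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, sub / exp, 0.0)
    if np.allclose(oe, oe.flat[0]):
        raise ValueError("degenerate observed/expected matrix")
    corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    vals, vecs = np.linalg.eigh(corr)
    pc1 = vecs[:, -1]
    out = np.full(m.shape[0], np.nan)
    out[informative] = pc1
    if reference is not None:
        ref = np.asarray(reference, dtype=float)[informative]
        if np.corrcoef(pc1, ref)[0, 1] < 0:
            out = -out
    return out


def compare_compartments(
    tracks_a: dict[str, np.ndarray], tracks_b: dict[str, np.ndarray]
) -> tuple[dict[str, float], float]:
    """Per-chromosome Pearson r between PC1 tracks, plus the median."""
    rs: dict[str, float] = {}
    for chrom in tracks_a:
        a, b = tracks_a[chrom], tracks_b[chrom]
        ok = ~(np.isnan(a) | np.isnan(b))
        rs[chrom] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return rs, float(np.median(list(rs.values())))
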