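"""Replication architecture from nucleotide and coding-strand skews.

On a circular bacterial chromosome the leading strand is enriched in G
over C and T over A, and in coding sequences.  The cumulative (G-C),
(T-A) and coding-direction skews therefore rise along one replichore and
fall along the other, with global extrema at the replication origin and
terminus.  This module computes those curves, calls the terminus (as a
point, or as an extended "terminal region" when the skew plateaus and
the strand-coding bias vanishes), partitions genes into replichore x
strand classes, and emits the strand-bias summary table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import AnnotatedGenome, GeneFeature, coding_genes

__all__ = [
    "SkewCurve",
    "TerminusCall",
    "base_skew_cumulative",
    "coding_density_cumulative",
    "combined_skew",
    "locate_terminus",
    "detect_terminal_region",
    "assign_replichores",
    "strand_bias_row",
    "strand_bias_table",
    "terminus_locus_listing",
    "call_terminus",
]

REPLICHORE_CLASSES = ("right_fwd", "right_rev", "left_rev", "left_fwd")


class NoSkewSignalError(ValueError):
    """Raised when no skew curve rises above random-walk noise."""


@dataclass
class SkewCurve:
    """A cumulative skew sampled at increasing genome positions."""

    positions: np.ndarray
    values: np.ndarray
    kind: str  # GC | TA | coding_density | combined

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values differ in length")
        if len(self.positions) == 0:
            raise ValueError("empty skew curve")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def value_range(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass
class TerminusCall:
    """Origin/terminus prediction with the curves that justify it."""

    terminus_bp: int
    origin_bp: int
    region: tuple[int, int] | None = None
    is_region: bool = False
    epsilon_used: float | None = None
    curves: dict[str, SkewCurve] = field(default_factory=dict)


_PAIR_INCREMENTS = {
    # first base of the pair counts +1, second -1
    "GC": ("G", "C"),
    "TA": ("T", "A"),
}


def base_skew_cumulative(seq: str, pair: str, stride: int = 1000) -> SkewCurve:
    """Cumulative base-composition skew of a sequence.

    ``pair`` is "GC" (increment +1 per G, -1 per C) or "TA" (+1 per T,
    -1 per A); other bases contribute 0.  The running sum is stored
    every ``stride`` bases plus at the final base; positions are the
    number of bases consumed (1-based bp).
    """
    if not seq:
        raise ValueError("empty sequence")
    if pair not in _PAIR_INCREMENTS:
        raise ValueError(f"pair must be GC or TA, got {pair!r}")
    plus, minus = _PAIR_INCREMENTS[pair]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    inc = np.zeros(len(arr), dtype=np.int64)
    inc[arr == ord(plus)] = 1
    inc[arr == ord(minus)] = -1
    cum = np.cumsum(inc)
    idx = np.arange(stride - 1, len(seq), stride)
    if len(idx) == 0 or idx[-1] != len(seq) - 1:
        idx = np.append(idx, len(seq) - 1)
    return SkewCurve(positions=idx + 1, values=cum[idx], kind=pair)


def base_skew_cumulative_cds3(
    genome: AnnotatedGenome, pair: str, stride: int = 1000
) -> SkewCurve:
    """Cumulative skew counted only at third codon positions of CDS.

    Third positions are under the weakest selective constraint and show
    the replication-strand mutational bias most cleanly; this mode
    masks everything else to zero and accumulates as usual.  Both modes
    should agree on extremum location for strongly skewed genomes.
    """
    seq = genome.sequence
    if not seq:
        raise ValueError("empty sequence")
    plus, minus = _PAIR_INCREMENTS[pair]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    inc = np.zeros(len(arr), dtype=np.int64)
    mask = np.zeros(len(arr), dtype=bool)
    for g in coding_genes(genome):
        if g.strand == +1:
            mask[np.arange(g.start + 2, g.end, 3)] = True
        else:
            # third codon positions read 5'->3' on the reverse strand
            mask[np.arange(g.end - 3, g.start - 1, -3)] = True
    inc[(arr == ord(plus)) & mask] = 1
    inc[(arr == ord(minus)) & mask] = -1
    cum = np.cumsum(inc)
    idx = np.arange(stride - 1, len(seq), stride)
    if len(idx) == 0 or idx[-1] != len(seq) - 1:
        idx = np.append(idx, len(seq) - 1)
    return SkewCurve(positions=idx + 1, values=cum[idx], kind=pair)


def coding_density_cumulative(genes: list[GeneFeature]) -> SkewCurve:
    """Cumulative coding-direction skew: +1 per forward gene, -1 per reverse.

    Genes must be sorted by start; positions are gene midpoints.
    """
    if not genes:
        raise ValueError("no genes")
    starts = [g.start for g in genes]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("genes must be sorted by start coordinate")
    inc = np.array([g.strand for g in genes], dtype=float)
    mids = np.array([g.midpoint for g in genes])
    # collapse duplicate midpoints (overlapping genes) to keep positions
    # strictly increasing
    cum = np.cumsum(inc)
    keep = np.append(np.diff(mids) > 0, True)
    return SkewCurve(positions=mids[keep], values=cum[keep], kind="coding_density")


def _minmax_scale(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def combined_skew(
    curves: list[SkewCurve], weights: dict[str, float] | None = None
) -> SkewCurve:
    """Weighted sum of skew curves on a shared grid.

    Each curve is linearly interpolated onto the union of all sampled
    positions and min-max scaled to [-1, 1] before weighting, so that a
    strongly counted skew (per-base) cannot drown a sparsely counted one
    (per-gene).  Default weights are 1 for every kind.
    """
    if not curves:
        raise ValueError("no curves to combine")
    weights = weights or {}
    grid = np.unique(np.concatenate([c.positions for c in curves]))
    total = np.zeros(len(grid))
    for c in curves:
        w = weights.get(c.kind, 1.0)
        resampled = np.interp(grid, c.positions, c.values)
        total += w * _minmax_scale(resampled)
    return SkewCurve(positions=grid, values=total, kind="combined")


def locate_terminus(curve: SkewCurve) -> TerminusCall:
    """Call terminus and origin from the global extrema of a skew curve.

    The extremum whose value lies farther from the mean of the curve's
    endpoint values is the terminus; the opposite extremum is the
    origin.  Ties break to the smallest coordinate.
    """
    v = curve.values
    if curve.value_range == 0:
        raise ValueError("no skew signal: curve is constant")
    i_max = int(np.argmax(v))  # argmax/argmin take the first = smallest coord
    i_min = int(np.argmin(v))
    endpoint_mean = (v[0] + v[-1]) / 2.0
    if abs(v[i_max] - endpoint_mean) >= abs(v[i_min] - endpoint_mean):
        i_ter, i_ori = i_max, i_min
    else:
        i_ter, i_ori = i_min, i_max
    return TerminusCall(
        terminus_bp=int(curve.positions[i_ter]),
        origin_bp=int(curve.positions[i_ori]),
        curves={curve.kind: curve},
    )


def _windowed_forward_fraction(
    genes: list[GeneFeature], window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Centered rolling forward-strand fraction over ``window`` genes."""
    mids = np.array([g.midpoint for g in genes])
    fwd = np.array([1.0 if g.strand == +1 else 0.0 for g in genes])
    frac = (
        pd.Series(fwd)
        .rolling(window, center=True, min_periods=max(1, window // 2))
        .mean()
        .to_numpy()
    )
    order = np.argsort(mids, kind="stable")
    return mids[order], frac[order]


def _close_gaps(ok: np.ndarray, positions: np.ndarray, max_gap_bp: float) -> np.ndarray:
    """Fill False runs spanning at most ``max_gap_bp`` between True runs."""
    out = ok.copy()
    idx = np.nonzero(ok)[0]
    if len(idx) < 2:
        return out
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a > 1 and positions[b] - positions[a] <= max_gap_bp:
            out[a:b] = True
    return out


def detect_terminal_region(
    curve: SkewCurve,
    genes: list[GeneFeature] | None,
    call: TerminusCall | None = None,
    epsilon: float = 0.02,
    bias_band: tuple[float, float] = (0.40, 0.60),
    window: int = 20,
    region_min: int = 10_000,
    max_gap_bp: float | None = None,
) -> TerminusCall:
    """Extend a point terminus to a terminal region where the skew plateaus.

    The region is the maximal contiguous interval around the called
    terminus on which (a) the combined skew stays within ``epsilon`` x
    curve range of its terminus value and (b) the windowed forward-
    strand gene fraction sits inside ``bias_band`` (no strand-coding
    bias).  A window of n genes estimates the forward fraction with a
    binomial sampling error of 0.5/sqrt(n) (~0.11 at the default 20),
    so the band is widened to at least two of those standard deviations
    and failing stretches shorter than ``max_gap_bp`` (default 3/4 of
    the window's genomic span) are bridged before expansion — otherwise
    single noisy windows inside a genuinely unbiased plateau would
    truncate it.  The call is reported as a region only when wider than
    ``region_min`` bp.  The detector's resolution is about one window
    span: widths below that are not meaningful, and a sharp terminus
    can carry an apparent region of that order.
    """
    if call is None:
        call = locate_terminus(curve)
    i_ter = int(np.argmin(np.abs(curve.positions - call.terminus_bp)))
    band = epsilon * curve.value_range
    ok = np.abs(curve.values - curve.values[i_ter]) <= band
    if genes:
        mids, frac = _windowed_forward_fraction(genes, window)
        frac_on_grid = np.interp(curve.positions, mids, frac)
        center = (bias_band[0] + bias_band[1]) / 2.0
        half = (bias_band[1] - bias_band[0]) / 2.0
        half = max(half, 2 * 0.5 / np.sqrt(window))  # >= 2 binomial sd
        ok &= np.abs(frac_on_grid - center) <= half
        if max_gap_bp is None:
            spacing = float(np.median(np.diff(mids))) if len(mids) > 1 else 1000.0
            max_gap_bp = window * spacing * 0.75
        ok = _close_gaps(ok, curve.positions, max_gap_bp)
        ok[i_ter] = True  # the terminus itself always belongs to its region
    lo = i_ter
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i_ter
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    region = (int(curve.positions[lo]), int(curve.positions[hi]))
    width = region[1] - region[0]
    return TerminusCall(
        terminus_bp=call.terminus_bp,
        origin_bp=call.origin_bp,
        region=region,
        is_region=width > region_min,
        epsilon_used=epsilon,
        curves=call.curves,
    )


def _skew_snr(curve: SkewCurve, n_steps: int) -> float:
    """Curve range in units of the null random-walk scale sqrt(steps).

    A skewless sequence still produces a +/-1 random walk whose range
    grows like sqrt(number of contributing steps); a genuine replication
    skew grows linearly and towers over it.
    """
    if n_steps <= 0:
        return 0.0
    return curve.value_range / np.sqrt(n_steps)


def call_terminus(
    genome: AnnotatedGenome,
    stride: int = 1000,
    weights: dict[str, float] | None = None,
    epsilon: float = 0.02,
    origin_override: int | None = None,
    region_kwargs: dict | None = None,
    snr_min: float = 5.0,
) -> TerminusCall:
    """Full terminus call for one genome: skews, combination, point + region.

    Raises :class:`NoSkewSignalError` when every component curve's range
    is below ``snr_min`` random-walk standard deviations — i.e. the
    genome carries no detectable replication-strand asymmetry.
    """
    genes = coding_genes(genome)
    seq = genome.sequence
    curves = [
        base_skew_cumulative(seq, "GC", stride=stride),
        base_skew_cumulative(seq, "TA", stride=stride),
    ]
    steps = [
        seq.count("G") + seq.count("C"),
        seq.count("T") + seq.count("A"),
    ]
    if genes:
        curves.append(coding_density_cumulative(genes))
        steps.append(len(genes))
    snrs = {c.kind: _skew_snr(c, n) for c, n in zip(curves, steps)}
    if all(v < snr_min for v in snrs.values()):
        raise NoSkewSignalError(
            "no skew signal: all curves within random-walk noise "
            f"(snr {', '.join(f'{k}={v:.1f}' for k, v in snrs.items())}, "
            f"threshold {snr_min})"
        )
    combined = combined_skew(curves, weights)
    call = locate_terminus(combined)
    call = detect_terminal_region(
        combined, genes, call=call, epsilon=epsilon, **(region_kwargs or {})
    )
    if origin_override is not None:
        call.origin_bp = int(origin_override)
    call.curves = {c.kind: c for c in curves}
    call.curves["combined"] = combined
    return call


def assign_replichores(
    genome: AnnotatedGenome, call: TerminusCall
) -> dict[str, str]:
    """Classify each coding gene into replichore x strand.

    The right replichore is the arc from origin to terminus traversed in
    increasing coordinates (modulo genome length); by convention it
    should be the longer arc — a warning is emitted if not.  A gene
    whose midpoint falls exactly on the terminus is assigned left.
    """
    L = genome.length_bp
    ori, ter = call.origin_bp % L, call.terminus_bp % L
    right_len = (ter - ori) % L
    if right_len < L - right_len:
        warnings.warn(
            f"{genome.organism_label}: right replichore ({right_len} bp) is "
            "shorter than the left — unusual origin/terminus geometry",
            stacklevel=2,
        )

    def in_right(mid: float) -> bool:
        return 0 < (mid - ori) % L < right_len

    out: dict[str, str] = {}
    for g in coding_genes(genome):
        mid = g.midpoint % L
        if (mid - ori) % L == right_len:
            warnings.warn(
                f"gene {g.gene_id} midpoint exactly at terminus; assigned left",
                stacklevel=2,
            )
        side = "right" if in_right(mid) else "left"
        out[g.gene_id] = f"{side}_{'fwd' if g.strand == +1 else 'rev'}"
    return out


def _round_half_away(x: float, ndigits: int = 1) -> float:
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def strand_bias_row(organism_label: str, class_counts: dict[str, int]) -> dict:
    """One summary row from the four replichore x strand class counts.

    Percentages are of the total coding genes, rounded half away from
    zero to one decimal.
    """
    missing = set(REPLICHORE_CLASSES) - set(class_counts)
    if missing:
        raise ValueError(f"missing classes: {sorted(missing)}")
    total = sum(class_counts[c] for c in REPLICHORE_CLASSES)
    if total == 0:
        raise ValueError("no coding genes")
    fwd = class_counts["right_fwd"] + class_counts["left_fwd"]
    rev = class_counts["right_rev"] + class_counts["left_rev"]
    row = {"organism": organism_label, "total_coding_genes": total}
    for c in REPLICHORE_CLASSES:
        row[c] = class_counts[c]
        row[f"{c}_pct"] = _round_half_away(100.0 * class_counts[c] / total)
    row["forward"] = fwd
    row["forward_pct"] = _round_half_away(100.0 * fwd / total)
    row["reverse"] = rev
    row["reverse_pct"] = _round_half_away(100.0 * rev / total)
    return row


def strand_bias_table(
    genomes_and_calls: list[tuple[AnnotatedGenome, TerminusCall]],
) -> pd.DataFrame:
    """Per-organism replichore x strand counts and percentages."""
    rows = []
    for genome, call in genomes_and_calls:
        classes = assign_replichores(genome, call)
        counts = {c: 0 for c in REPLICHORE_CLASSES}
        for cls in classes.values():
            counts[cls] += 1
        rows.append(strand_bias_row(genome.organism_label, counts))
    return pd.DataFrame(rows)


def terminus_locus_listing(
    genome: AnnotatedGenome, call: TerminusCall, flank_genes: int = 10
) -> list[dict]:
    """The genes flanking the terminus, as a plain-text-ready listing.

    Returns up to ``flank_genes`` genes on each side of the terminus in
    coordinate order; a gene containing the terminus is listed once, on
    the side where its midpoint lies.
    """
    genes = coding_genes(genome)
    before = [g for g in genes if g.midpoint < call.terminus_bp]
    after = [g for g in genes if g.midpoint >= call.terminus_bp]
    picked = [(g, "before") for g in before[-flank_genes:]] + [
        (g, "after") for g in after[:flank_genes]
    ]
    return [
        {
            "gene_id": g.gene_id,
            "side": side,
            "start": g.start,
            "end": g.end,
            "strand": "+" if g.strand == +1 else "-",
            "product": g.product,
        }
        for g, side in picked
    ]
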