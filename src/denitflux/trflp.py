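"""T-RFLP fingerprint processing and multiple alignment.

Terminal restriction fragment length polymorphism (T-RFLP) profiles a
microbial community as a set of fluorescence peaks, one per terminal
restriction fragment (T-RF), each characterised by fragment size (bp),
peak area and peak height. Size calling carries sub-bp error, so the
"same" fragment drifts between samples and profiles must be aligned into
cross-sample bins before community statistics can be computed.

The pipeline implemented here:

1. :func:`smooth_and_merge` — collapse double/shoulder peaks closer than
   a merge window into single peaks;
2. :func:`relativize` — scale each profile so areas sum to 1 and heights
   sum to 1;
3. :func:`classify_noise` — iterative signal/noise separation using
   standard deviations about a zero baseline, pooled across samples;
4. :func:`align_pair` — dynamic-programming alignment of two size-sorted
   peak lists under a size/area/height dissimilarity with a gap cost;
5. :func:`build_alignment` — random-order incremental multiple alignment
   against a running consensus of bin-averaged peaks;
6. :func:`refine_alignment` — leave-one-out realignment passes accepted
   while the overall score improves;
7. :func:`combine_enzymes` — concatenate the bin tables of the two
   restriction digests of one gene.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Profile",
    "AlignParams",
    "Alignment",
    "PairAlignment",
    "smooth_and_merge",
    "relativize",
    "classify_noise",
    "denoise",
    "peak_dissimilarity",
    "align_pair",
    "build_alignment",
    "refine_alignment",
    "combine_enzymes",
]

INFEASIBLE = math.inf


@dataclass
class Peak:
    """One detected fragment: size (bp, fractional), area, height."""

    size: float
    area: float
    height: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("peak size must be positive")
        if self.area < 0 or self.height < 0:
            raise ValueError("peak area and height must be non-negative")


@dataclass
class Profile:
    """A per-sample, per-gene, per-enzyme size-sorted peak list."""

    sample_id: str
    gene: str
    enzyme: str
    peaks: list[Peak]
    normalized: bool = False

    def __post_init__(self) -> None:
        sizes = [p.size for p in self.peaks]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("profile peaks must be strictly ascending in size")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.peaks])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks])


@dataclass
class AlignParams:
    """Tunable knobs of the processing and alignment pipeline.

    merge_window: peaks closer than this (bp) are merged as shoulders.
    max_drift: largest size difference (bp) two peaks may have and still
        be considered the same fragment.
    w_size / w_area / w_height: dissimilarity weights; with sizes in bp
    and relativized signals in [0, 1] the default unit weights put the
    three terms on comparable scales.
    gap_cost: cost of leaving one peak unmatched; a match is preferred
        over two gaps whenever its dissimilarity is below 2 * gap_cost.
    noise_k: signal threshold in baseline standard deviations.
    noise_require_both: if True a peak must exceed the threshold in both
        area and height to be signal; if False either suffices.
    """

    merge_window: float = 0.5
    max_drift: float = 1.0
    w_size: float = 1.0
    w_area: float = 1.0
    w_height: float = 1.0
    gap_cost: float = 0.75
    noise_k: float = 3.0
    noise_require_both: bool = True
    seed: int = 0
    max_refine_iters: int = 20

    def __post_init__(self) -> None:
        for name in ("merge_window", "max_drift", "w_size", "w_area", "w_height", "gap_cost", "noise_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_drift < self.merge_window:
            raise ValueError("max_drift must be >= merge_window")


def smooth_and_merge(profile: Profile, params: AlignParams) -> Profile:
    """Collapse double/shoulder peaks closer than the merge window.

    Repeatedly merges the closest pair of peaks whose size difference is
    below ``merge_window``; the merged peak takes the area-weighted mean
    size, the summed area, the maximum height, and the label of the
    larger-area member. Merging closest-first makes the outcome of peak
    chains deterministic.
    """
    if profile.normalized:
        raise ValueError("merge operates on raw (unnormalized) profiles")
    peaks = [replace(p) for p in profile.peaks]
    while len(peaks) > 1:
        gaps = [peaks[i + 1].size - peaks[i].size for i in range(len(peaks) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] >= params.merge_window:
            break
        a, b = peaks[i], peaks[i + 1]
        total = a.area + b.area
        size = (a.size * a.area + b.size * b.area) / total if total > 0 else 0.5 * (a.size + b.size)
        label = a.label if a.area >= b.area else b.label
        peaks[i : i + 2] = [Peak(size=size, area=total, height=max(a.height, b.height), label=label)]
    return Profile(profile.sample_id, profile.gene, profile.enzyme, peaks, normalized=False)


def relativize(profile: Profile) -> Profile:
    """Divide areas and heights by their within-profile sums."""
    if profile.normalized:
        return profile
    if not profile.peaks:
        raise ValueError("cannot relativize an empty profile")
    area_sum = sum(p.area for p in profile.peaks)
    height_sum = sum(p.height for p in profile.peaks)
    if area_sum <= 0 or height_sum <= 0:
        raise ValueError("profile has zero total area or height")
    peaks = [
        Peak(p.size, p.area / area_sum, p.height / height_sum, p.label)
        for p in profile.peaks
    ]
    return Profile(profile.sample_id, profile.gene, profile.enzyme, peaks, normalized=True)


def classify_noise(profiles: Sequence[Profile], params: AlignParams) -> dict[str, np.ndarray]:
    """Iterative signal/noise classification pooled across samples.

    Over all peaks of one (gene, enzyme) not yet flagged as signal, the
    standard deviation about a theoretical baseline of zero relative
    fluorescence is ``sigma = sqrt(mean(x^2))``, computed separately for
    relative areas and heights. Peaks at or above ``noise_k * sigma``
    (in both metrics by default, see ``noise_require_both``) are flagged
    signal and removed from the pool; sigma is recomputed and the rule
    reapplied until no new peak is flagged. Unflagged peaks are noise.

    Returns a mapping sample_id -> boolean array (True = signal)
    parallel to each profile's peak list.
    """
    if not profiles:
        return {}
    key = {(p.gene, p.enzyme) for p in profiles}
    if len(key) != 1:
        raise ValueError("classify_noise expects profiles of a single (gene, enzyme)")
    if any(not p.normalized for p in profiles):
        raise ValueError("profiles must be relativized before noise classification")

    areas = np.concatenate([p.areas for p in profiles]) if profiles else np.array([])
    heights = np.concatenate([p.heights for p in profiles])
    signal = np.zeros(areas.size, dtype=bool)
    while True:
        pool = ~signal
        if not pool.any():
            break
        sd_a = math.sqrt(float(np.mean(areas[pool] ** 2)))
        sd_h = math.sqrt(float(np.mean(heights[pool] ** 2)))
        big_a = areas >= params.noise_k * sd_a
        big_h = heights >= params.noise_k * sd_h
        hit = (big_a & big_h) if params.noise_require_both else (big_a | big_h)
        new = hit & pool
        if not new.any():
            break
        signal |= new

    out: dict[str, np.ndarray] = {}
    start = 0
    for p in profiles:
        n = len(p.peaks)
        out[p.sample_id] = signal[start : start + n].copy()
        start += n
    return out


def denoise(profiles: Sequence[Profile], params: AlignParams) -> list[Profile]:
    """Drop noise peaks; profiles that lose all peaks are dropped too."""
    flags = classify_noise(profiles, params)
    kept = []
    for p in profiles:
        mask = flags[p.sample_id]
        peaks = [pk for pk, keep in zip(p.peaks, mask) if keep]
        if peaks:
            kept.append(Profile(p.sample_id, p.gene, p.enzyme, peaks, normalized=p.normalized))
    return kept


def peak_dissimilarity(p: Peak, q: Peak, params: AlignParams) -> float:
    """Weighted L1 dissimilarity in size, area and height.

    Returns ``inf`` (infeasible) when the size difference exceeds
    ``max_drift``.
    """
    dsize = abs(p.size - q.size)
    if dsize > params.max_drift:
        return INFEASIBLE
    return (
        params.w_size * dsize
        + params.w_area * abs(p.area - q.area)
        + params.w_height * abs(p.height - q.height)
    )


@dataclass
class PairAlignment:
    """Result of aligning two peak sequences: matched index pairs,
    unmatched indices on either side, and the total cost."""

    matches: list[tuple[int, int]]
    unmatched_p: list[int]
    unmatched_q: list[int]
    cost: float


def _peaks_of(x: Union[Profile, Sequence[Peak]]) -> list[Peak]:
    peaks = list(x.peaks) if isinstance(x, Profile) else list(x)
    sizes = [p.size for p in peaks]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("peaks must be strictly size-sorted")
    return peaks


def align_pair(P: Union[Profile, Sequence[Peak]], Q: Union[Profile, Sequence[Peak]], params: AlignParams) -> PairAlignment:
    """Global DP alignment of two size-sorted peak sequences.

    Minimises the sum of match dissimilarities plus ``gap_cost`` per
    unmatched peak over all non-crossing matchings whose matched pairs
    are feasible (size difference within ``max_drift``). Ties are broken
    deterministically: match preferred over gap, then gap in P over gap
    in Q.
    """
    pp, qq = _peaks_of(P), _peaks_of(Q)
    n, m = len(pp), len(qq)
    g = params.gap_cost
    M = np.empty((n + 1, m + 1))
    M[0, :] = np.arange(m + 1) * g
    M[:, 0] = np.arange(n + 1) * g
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=diag, 1=up(gap in P), 2=left(gap in Q)
    move[0, 1:] = 2
    move[1:, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = peak_dissimilarity(pp[i - 1], qq[j - 1], params)
            c_match = M[i - 1, j - 1] + d
            c_up = M[i - 1, j] + g
            c_left = M[i, j - 1] + g
            best = min(c_match, c_up, c_left)
            M[i, j] = best
            if c_match <= best:
                move[i, j] = 0
            elif c_up <= best:
                move[i, j] = 1
            else:
                move[i, j] = 2
    # traceback
    matches: list[tuple[int, int]] = []
    un_p: list[int] = []
    un_q: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0 and i > 0 and j > 0:
            matches.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == 1 and i > 0:
            un_p.append(i - 1)
            i -= 1
        else:
            un_q.append(j - 1)
            j -= 1
    matches.reverse()
    un_p.reverse()
    un_q.reverse()
    return PairAlignment(matches, un_p, un_q, float(M[n, m]))


@dataclass
class _Bin:
    """One cross-sample bin: member peaks keyed by sample."""

    members: dict[str, Peak] = field(default_factory=dict)

    @property
    def occupancy(self) -> int:
        return len(self.members)

    @property
    def consensus(self) -> Peak:
        sizes = [p.size for p in self.members.values()]
        areas = [p.area for p in self.members.values()]
        heights = [p.height for p in self.members.values()]
        return Peak(float(np.mean(sizes)), float(np.mean(areas)), float(np.mean(heights)))


@dataclass
class Alignment:
    """Multiple alignment of one (gene, enzyme): bins x samples.

    Bins carry the unweighted mean size/area/height of their current
    members (one peak per sample at most). The overall score is the sum,
    over all member peaks, of the peak-to-bin-consensus dissimilarity;
    a peak alone in its bin contributes the gap cost instead, so the
    score penalises fragmenting the alignment into singleton bins.
    """

    gene: str
    enzyme: str
    sample_ids: list[str]
    bins: list[_Bin]
    params: AlignParams
    score: float = math.nan
    score_history: list[float] = field(default_factory=list)

    def sort_bins(self) -> None:
        self.bins.sort(key=lambda b: b.consensus.size)

    def compute_score(self) -> float:
        total = 0.0
        for b in self.bins:
            if b.occupancy == 1:
                total += self.params.gap_cost
                continue
            cons = b.consensus
            for peak in b.members.values():
                d = peak_dissimilarity(peak, cons, self.params)
                total += self.params.gap_cost if math.isinf(d) else d
        return total

    def validate(self) -> None:
        sizes = [b.consensus.size for b in self.bins]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise AssertionError("bin consensus sizes must be strictly increasing")
        if not math.isclose(self.score, self.compute_score(), rel_tol=0, abs_tol=1e-9):
            raise AssertionError("stored score does not match recomputed score")

    def consensus_peaks(self) -> list[Peak]:
        return [b.consensus for b in self.bins]

    def to_frame(self, value: str = "area", prefix: str = "") -> pd.DataFrame:
        """Wide sample x bin table of relative areas (or heights/sizes)."""
        self.sort_bins()
        cols = [f"{prefix}{b.consensus.size:.2f}" for b in self.bins]
        data = np.zeros((len(self.sample_ids), len(self.bins)))
        for j, b in enumerate(self.bins):
            for sid, peak in b.members.items():
                data[self.sample_ids.index(sid), j] = getattr(peak, value)
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols)

    def bin_summary(self) -> pd.DataFrame:
        self.sort_bins()
        rows = [
            {
                "bin_id": i,
                "consensus_size": b.consensus.size,
                "mean_area": b.consensus.area,
                "mean_height": b.consensus.height,
                "occupancy": b.occupancy,
            }
            for i, b in enumerate(self.bins)
        ]
        return pd.DataFrame(rows)

    def membership(self) -> dict[tuple[str, float], int]:
        """(sample_id, peak size) -> bin index, after size-sorting bins."""
        self.sort_bins()
        out = {}
        for i, b in enumerate(self.bins):
            for sid, peak in b.members.items():
                out[(sid, peak.size)] = i
        return out


def _insert_profile(aln: Alignment, profile: Profile) -> None:
    """Align one profile against the consensus and update the bins."""
    aln.sort_bins()
    consensus = aln.consensus_peaks()
    pair = align_pair(consensus, profile, aln.params)
    for ci, pj in pair.matches:
        aln.bins[ci].members[profile.sample_id] = profile.peaks[pj]
    for pj in pair.unmatched_q:
        aln.bins.append(_Bin(members={profile.sample_id: profile.peaks[pj]}))
    aln.sort_bins()


def build_alignment(profiles: Sequence[Profile], params: AlignParams) -> Alignment:
    """Random-order incremental multiple alignment.

    A seeded RNG orders the profiles; the first two are aligned pairwise
    and converted to consensus bins (averaged size/area/height), then
    each remaining profile is aligned against the running consensus,
    matched peaks joining their bin and unmatched peaks opening new
    bins. Deterministic under ``params.seed``.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("multiple alignment needs at least 2 profiles")
    keys = {(p.gene, p.enzyme) for p in profiles}
    if len(keys) != 1:
        raise ValueError("profiles must share one (gene, enzyme)")
    if any(not p.normalized for p in profiles):
        raise ValueError("profiles must be relativized before alignment")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")

    rng = np.random.default_rng(params.seed)
    order = rng.permutation(len(profiles))
    gene, enzyme = profiles[0].gene, profiles[0].enzyme
    aln = Alignment(gene=gene, enzyme=enzyme, sample_ids=sorted(ids), bins=[], params=params)

    first = profiles[order[0]]
    aln.bins = [_Bin(members={first.sample_id: pk}) for pk in first.peaks]
    for idx in order[1:]:
        _insert_profile(aln, profiles[idx])
    aln.score = aln.compute_score()
    aln.score_history = [aln.score]
    return aln


def _remove_sample(aln: Alignment, sample_id: str) -> None:
    for b in aln.bins:
        b.members.pop(sample_id, None)
    aln.bins = [b for b in aln.bins if b.occupancy > 0]
    aln.sort_bins()


def refine_alignment(aln: Alignment, profiles: Sequence[Profile], params: AlignParams) -> Alignment:
    """Leave-one-out refinement of a multiple alignment.

    Each pass removes every sample in seeded random order, recomputes
    bin averages without it, and realigns it to the remaining consensus.
    A pass is kept only if the overall score strictly decreased; the
    first non-improving pass is reverted and refinement stops, subject
    to a hard cap of ``max_refine_iters`` passes.
    """
    by_id = {p.sample_id: p for p in profiles}
    if set(by_id) != set(aln.sample_ids):
        raise ValueError("profiles do not match the alignment's samples")
    aln = copy.deepcopy(aln)
    if math.isnan(aln.score):
        aln.score = aln.compute_score()
        aln.score_history = [aln.score]
    rng = np.random.default_rng(params.seed + 1)

    for _ in range(params.max_refine_iters):
        snapshot = copy.deepcopy(aln.bins)
        prev = aln.score
        for sid in rng.permutation(aln.sample_ids):
            _remove_sample(aln, str(sid))
            _insert_profile(aln, by_id[str(sid)])
        new_score = aln.compute_score()
        if new_score < prev:
            aln.score = new_score
            aln.score_history.append(new_score)
        else:
            aln.bins = snapshot
            break
    return aln


def combine_enzymes(alnA: Alignment, alnB: Alignment) -> pd.DataFrame:
    """Concatenate the bin tables of two enzyme digests of one gene.

    Columns are enzyme-prefixed bin ids; values are relative peak areas;
    both alignments must cover the same sample set.
    """
    if set(alnA.sample_ids) != set(alnB.sample_ids):
        raise ValueError("alignments cover different sample sets")
    a = alnA.to_frame(prefix=f"{alnA.enzyme}_")
    b = alnB.to_frame(prefix=f"{alnB.enzyme}_").loc[a.index]
    return pd.concat([a, b], axis=1)
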