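"""Overlap enrichment of spot sets against genomic annotations.

The null distribution comes from bootstrapping width- and
chromosome-matched random regions over the unmasked genome: for each of B
replicates, |spots| regions are placed uniformly over the eligible space
(excluding blacklisted bins and the called spots themselves) and the
overlap proportion with the annotation recomputed. The empirical p-value
uses the add-one formula, so it is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationSet, intervals_overlap_any, merge_intervals


def _merged_by_chrom(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in df.groupby("chrom")
    }


def _overlap_flags(spots: pd.DataFrame, merged: dict[str, np.ndarray]) -> np.ndarray:
    flags = np.zeros(len(spots), dtype=bool)
    for chrom, sub in spots.reset_index(drop=True).groupby("chrom"):
        ref = merged.get(chrom)
        if ref is None or not len(ref):
            continue
        flags[sub.index.to_numpy()] = intervals_overlap_any(
            sub["start"].to_numpy(), sub["end"].to_numpy(), ref[:, 0], ref[:, 1]
        )
    return flags


def overlap_proportion(spots: pd.DataFrame, annotation: AnnotationSet) -> float:
    """Fraction of spots overlapping >= 1 annotation interval by >= 1 bp."""
    if len(spots) == 0:
        raise ValueError("overlap proportion undefined for an empty spot set")
    return float(_overlap_flags(spots, _merged_by_chrom(annotation.df)).mean())


@dataclass
class _SlotSpace:
    """Uniform sampler over all legal placements of a fixed-width interval."""

    chrom: str
    width: int
    gap_starts: np.ndarray   # per eligible gap: first legal start
    slot_counts: np.ndarray  # per gap: number of legal starts
    cum: np.ndarray

    @property
    def n_slots(self) -> int:
        return int(self.cum[-1])

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.integers(0, self.n_slots, size=n)
        gi = np.searchsorted(self.cum, u, side="right") - 1
        return self.gap_starts[gi] + (u - self.cum[gi])


def _slot_space(
    chrom: str, size: int, width: int, exclusions: pd.DataFrame
) -> _SlotSpace:
    sub = exclusions[exclusions["chrom"] == chrom] if len(exclusions) else exclusions
    if len(sub):
        merged = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    else:
        merged = np.empty((0, 2), dtype=np.int64)
    gaps = []
    prev = 0
    for s, e in merged:
        if s > prev:
            gaps.append((prev, min(s, size)))
        prev = max(prev, e)
    if prev < size:
        gaps.append((prev, size))
    gap_starts, counts = [], []
    for s, e in gaps:
        if e - s >= width:
            gap_starts.append(s)
            counts.append(e - s - width + 1)
    gap_starts = np.asarray(gap_starts, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(counts)])
    return _SlotSpace(chrom=chrom, width=width, gap_starts=gap_starts,
                      slot_counts=counts, cum=cum)


def sample_random_spots(
    n: int,
    width: int,
    sizes: Mapping[str, int],
    exclusions: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
    chrom: str | None = None,
) -> pd.DataFrame:
    """``n`` width-matched regions placed uniformly over eligible space.

    Eligible space is everything outside the (merged) exclusion intervals;
    placements never overlap an exclusion but may overlap each other, as in
    bootstrap resampling. Restrict to one chromosome with ``chrom``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if exclusions is None:
        exclusions = pd.DataFrame(columns=["chrom", "start", "end"])
    chroms = [chrom] if chrom is not None else list(sizes)
    spaces = [_slot_space(c, sizes[c], width, exclusions) for c in chroms]
    totals = np.array([sp.n_slots for sp in spaces], dtype=float)
    if totals.sum() < 1 or (n > 0 and totals.sum() == 0):
        raise ValueError(f"no eligible space for {n} regions of width {width}")
    picks = rng.choice(len(spaces), size=n, p=totals / totals.sum()) if len(spaces) > 1 \
        else np.zeros(n, dtype=int)
    rows = []
    for ci, sp in enumerate(spaces):
        k = int((picks == ci).sum())
        if k:
            starts = sp.draw(rng, k)
            rows.append(pd.DataFrame({"chrom": sp.chrom, "start": starts, "end": starts + width}))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end"])
    return out


@dataclass
class EnrichmentResult:
    """Observed overlap proportion against its bootstrap genome null."""

    spot_set: str
    annotation: str
    observed: float
    null: np.ndarray
    p_enrichment: float
    p_depletion: float
    p_two_sided: float
    null_mean: float
    coverage_fraction: float

    def summary(self) -> dict:
        return {
            "spot_set": self.spot_set,
            "annotation": self.annotation,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "coverage_fraction": self.coverage_fraction,
            "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion,
            "p_two_sided": self.p_two_sided,
            "B": len(self.null),
        }


def bootstrap_enrichment(
    spots: pd.DataFrame,
    annotation: AnnotationSet,
    sizes: Mapping[str, int],
    exclusions: pd.DataFrame | None = None,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    spot_set_name: str = "spots",
) -> EnrichmentResult:
    """Bootstrap test of spot-annotation overlap against random regions.

    Null regions are matched per chromosome and per width to the observed
    spot set and exclude blacklisted space plus the spots themselves.
    Empirical p = (1 + #{null >= observed}) / (B + 1), mirrored for
    depletion; two-sided is twice the smaller tail (capped at 1). The null
    mean estimates the "genome average" overlap proportion; the annotation's
    merged coverage fraction of the assembly is reported alongside.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a meaningful empirical p-value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    merged_ann = _merged_by_chrom(annotation.df)
    observed = float(_overlap_flags(spots, merged_ann).mean())

    if exclusions is None:
        exclusions = pd.DataFrame(columns=["chrom", "start", "end"])
    excl = pd.concat([exclusions[["chrom", "start", "end"]],
                      spots[["chrom", "start", "end"]]], ignore_index=True)

    groups = spots.assign(width=spots["end"] - spots["start"]).groupby(["chrom", "width"])
    spaces = {}
    counts = {}
    for (chrom, width), sub in groups:
        spaces[(chrom, width)] = _slot_space(chrom, sizes[chrom], int(width), excl)
        counts[(chrom, width)] = len(sub)
        if spaces[(chrom, width)].n_slots == 0:
            raise ValueError(f"no eligible space on {chrom} for width {width}")

    n_spots = len(spots)
    hits = np.zeros((B,), dtype=np.int64)
    for (chrom, width), sp in spaces.items():
        k = counts[(chrom, width)]
        starts = sp.draw(rng, B * k).reshape(B, k)
        ref = merged_ann.get(chrom)
        if ref is None or not len(ref):
            continue
        flat = starts.ravel()
        got = intervals_overlap_any(flat, flat + width, ref[:, 0], ref[:, 1])
        hits += got.reshape(B, k).sum(axis=1)
    null = hits / n_spots
    p_enr = (1 + int((null >= observed).sum())) / (B + 1)
    p_dep = (1 + int((null <= observed).sum())) / (B + 1)
    return EnrichmentResult(
        spot_set=spot_set_name,
        annotation=annotation.name,
        observed=observed,
        null=null,
        p_enrichment=p_enr,
        p_depletion=p_dep,
        p_two_sided=min(1.0, 2 * min(p_enr, p_dep)),
        null_mean=float(null.mean()),
        coverage_fraction=annotation.coverage_fraction(sizes),
    )


def count_interactions_per_spot(
    spots: pd.DataFrame,
    interactions: pd.DataFrame,
    anchor_bin: int | None = None,
) -> np.ndarray:
    """Per-spot count of interactions with >= 1 anchor overlapping the spot.

    When ``anchor_bin`` is given (e.g. 40000 for 40-kb contact maps), each
    spot is expanded to its containing anchor-resolution bin before the
    overlap test, matching how interaction anchors are reported.
    """
    sp = spots[["chrom", "start", "end"]].copy()
    if anchor_bin:
        sp["start"] = (sp["start"] // anchor_bin) * anchor_bin
        sp["end"] = sp["start"] + anchor_bin
    counts = np.zeros(len(sp), dtype=np.int64)
    sp = sp.reset_index(drop=True)
    for side in (("chrom1", "start1", "end1"), ("chrom2", "start2", "end2")):
        for chrom, sub in sp.groupby("chrom"):
            anchors = interactions[interactions[side[0]] == chrom]
            if anchors.empty:
                continue
            a_s = anchors[side[1]].to_numpy()
            a_e = anchors[side[2]].to_numpy()
            for i, s, e in zip(sub.index, sub["start"], sub["end"]):
                counts[i] += int(((a_s < e) & (a_e > s)).sum())
    return counts


def interaction_excess_test(
    spot_counts: np.ndarray, random_counts: np.ndarray
) -> tuple[float, float]:
    """One-sided rank-sum test that spots carry more interactions than
    matched random regions. Returns (statistic, p)."""
    stat, p = stats.mannwhitneyu(spot_counts, random_counts, alternative="greater")
    return float(stat), float(p)


def aggregate_signal(
    spots: pd.DataFrame, track: pd.DataFrame, sizes: Mapping[str, int]
) -> np.ndarray:
    """Mean per-base signal over each spot from a bedGraph-style track.

    Positions not covered by the track count as 0.
    """
    integrals = {}
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("start")
        pts = np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()])
        # prefix integral of the piecewise-constant track at breakpoints
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["value"].to_numpy(dtype=float)
        integrals[chrom] = (starts, ends, vals, np.concatenate([[0], np.cumsum((ends - starts) * vals)]))
    means = np.zeros(len(spots))
    for i, r in enumerate(spots.itertuples()):
        if r.chrom not in integrals:
            continue
        starts, ends, vals, cum = integrals[r.chrom]
        lo, hi = r.start, r.end
        j0 = np.searchsorted(ends, lo, side="right")
        j1 = np.searchsorted(starts, hi, side="left")
        total = 0.0
        for j in range(j0, j1):
            total += vals[j] * max(0, min(ends[j], hi) - max(starts[j], lo))
        means[i] = total / (hi - lo)
    return means


def compare_signal_groups(values: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Pairwise one-sided rank-sum comparisons of per-spot signal by group."""
    labels = np.asarray(labels)
    rows = []
    groups = sorted(set(labels))
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            stat, p = stats.mannwhitneyu(
                values[labels == a], values[labels == b], alternative="two-sided"
            )
            rows.append((a, b, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "pvalue"])


def category_composition(
    spots: pd.DataFrame, states: AnnotationSet
) -> pd.Series:
    """Fraction of spots assigned to each state label.

    A spot overlapping several labels is assigned to the label with the
    largest overlap, ties broken alphabetically; spots overlapping no state
    remain unassigned, so fractions sum to <= 1.
    """
    if "label" not in states.df.columns:
        raise ValueError("state annotation needs a 'label' column")
    labels = sorted(states.df["label"].unique())
    assigned = []
    for r in spots.itertuples():
        sub = states.df[states.df["chrom"] == r.chrom]
        ov = np.minimum(sub["end"].to_numpy(), r.end) - np.maximum(sub["start"].to_numpy(), r.start)
        best, best_ov = None, 0
        for lab, o in zip(sub["label"], ov):
            if o > best_ov or (o == best_ov and o > 0 and (best is None or lab < best)):
                best, best_ov = lab, o
        if best is not None:
            assigned.append(best)
    counts = pd.Series(assigned).value_counts() if assigned else pd.Series(dtype=int)
    return pd.Series({lab: counts.get(lab, 0) / len(spots) for lab in labels})
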