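"""Cohort-level aggregation: quality-based inclusion, profile envelopes,
average centerlines and summary tables.

Specimens are rated per section (three canals, three ampullae, common crus)
on a four-point damage scale:

    0  no obvious deviation
    1  membranous duct possibly detached from the bony labyrinth
    2  disrupted membranous duct or collapsed ampulla
    3  opened or missing segment of a canal

A section enters the bony-labyrinth analysis if its consensus score is <= 2
and the membranous analysis only if it is 0.  Envelopes report mean, sample
SD, min/max and quartiles per percent-grid point over the specimens with a
valid frame there; the contributing count n shrinks in junction-adjacent
regions, mirroring the reduced-sample hatched regions of per-position plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centerline import Centerline

SECTIONS = ("posterior", "superior", "lateral",
            "posterior_ampulla", "superior_ampulla", "lateral_ampulla",
            "common_crus")
BONY_SCORE_MAX = 2
MEMBRANOUS_SCORE_MAX = 0


@dataclass
class QualityScores:
    """Consensus scores per section for one specimen (values 0-3)."""

    scores: dict[str, int]

    def __post_init__(self) -> None:
        missing = [s for s in SECTIONS if s not in self.scores]
        if missing:
            raise ValueError(f"missing section scores: {missing}")
        bad = {k: v for k, v in self.scores.items() if v not in (0, 1, 2, 3)}
        if bad:
            raise ValueError(f"scores must be 0-3, got {bad}")

    def __getitem__(self, section: str) -> int:
        return self.scores[section]


def include_section(scores: QualityScores, section: str, compartment: str,
                    bony_max: int = BONY_SCORE_MAX,
                    membranous_max: int = MEMBRANOUS_SCORE_MAX) -> bool:
    """Inclusion rule: bony sections tolerate damage up to ``bony_max``;
    membranous sections only an untouched duct (score <= ``membranous_max``,
    default 0)."""
    s = scores[section]
    if compartment == "bony":
        return s <= bony_max
    if compartment in ("membranous", "endolymph"):
        return s <= membranous_max
    raise ValueError(f"unknown compartment {compartment!r}")


def consensus(ratings: dict[str, dict[str, int]],
              rule: str = "max") -> tuple[QualityScores, list[str]]:
    """Combine per-rater scores into a consensus.

    Where raters agree the common score is taken; disagreements are resolved
    by ``rule`` ('max' = most conservative, 'median', 'min') and reported in
    the returned list of flagged sections.
    """
    if not ratings:
        raise ValueError("need at least one rater")
    flagged = []
    out = {}
    for section in SECTIONS:
        vals = [r[section] for r in ratings.values()]
        if len(set(vals)) == 1:
            out[section] = vals[0]
            continue
        flagged.append(section)
        if rule == "max":
            out[section] = max(vals)
        elif rule == "min":
            out[section] = min(vals)
        elif rule == "median":
            out[section] = int(np.median(vals))
        else:
            raise ValueError(f"unknown consensus rule {rule!r}")
    return QualityScores(out), flagged


@dataclass
class CohortEnvelope:
    """Pointwise distribution of a profile quantity over the cohort."""

    percent: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    n: np.ndarray
    reduced_n: np.ndarray = field(default=None)   # below the coverage fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "percent": self.percent, "mean": self.mean, "sd": self.sd,
            "min": self.min, "max": self.max, "q1": self.q1, "q3": self.q3,
            "n": self.n, "reduced_n": self.reduced_n})


def aggregate(profiles: list[np.ndarray], percent: np.ndarray | None = None,
              coverage_fraction: float = 0.66) -> CohortEnvelope:
    """Envelope over per-specimen profiles sharing the percent grid.

    NaN marks invalid frames and simply removes that specimen from the
    statistics at that grid point.  SD uses the n-1 denominator (undefined,
    NaN, for n < 2); quartiles interpolate linearly between closest ranks.
    Grid points where fewer than ``coverage_fraction`` of the specimens
    contribute are flagged ``reduced_n`` (the hatched regions of
    per-position plots).
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    arr = np.vstack([np.asarray(p, dtype=float) for p in profiles])
    if percent is None:
        percent = np.linspace(0, 100, arr.shape[1])
    n = np.isfinite(arr).sum(axis=0)
    any_ = n > 0
    mean = np.full(arr.shape[1], np.nan)
    sd = np.full(arr.shape[1], np.nan)
    mn = np.full(arr.shape[1], np.nan)
    mx = np.full(arr.shape[1], np.nan)
    q1 = np.full(arr.shape[1], np.nan)
    q3 = np.full(arr.shape[1], np.nan)
    sub = arr[:, any_]
    mean[any_] = np.nanmean(sub, axis=0)
    mn[any_] = np.nanmin(sub, axis=0)
    mx[any_] = np.nanmax(sub, axis=0)
    q1[any_] = np.nanpercentile(sub, 25, axis=0)
    q3[any_] = np.nanpercentile(sub, 75, axis=0)
    two = n >= 2
    if two.any():
        sd[two] = np.nanstd(arr[:, two], axis=0, ddof=1)
    reduced = n < np.ceil(coverage_fraction * arr.shape[0])
    return CohortEnvelope(percent=np.asarray(percent, dtype=float), mean=mean,
                          sd=sd, min=mn, max=mx, q1=q1, q3=q3, n=n,
                          reduced_n=reduced)


def average_centerline(lines: list[Centerline]) -> Centerline:
    """Pointwise mean of co-registered centerlines on the percent grid."""
    if not lines:
        raise ValueError("no centerlines")
    if len(lines) == 1:
        return lines[0]
    grids = {len(l.points) for l in lines}
    if len(grids) != 1:
        raise ValueError("centerlines are not on a common grid")
    pts = np.mean([l.points for l in lines], axis=0)
    return Centerline(points=pts, canal=lines[0].canal,
                      compartment=lines[0].compartment)


def summary_length_table(lengths: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/Min/Max of centerline lengths per structure and compartment.

    ``lengths`` is tidy: columns (specimen, structure, compartment,
    length_mm).  Output is shaped like a per-compartment length table with
    structures as columns."""
    out = {}
    for comp, g in lengths.groupby("compartment"):
        t = g.groupby("structure")["length_mm"].agg(
            Mean="mean",
            SD=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan,
            Min="min", Max="max").T
        out[comp] = t
    return pd.concat(out, names=["compartment", "statistic"])


def summary_angle_table(angles: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of pairwise plane angles per compartment (tidy input with
    columns specimen, compartment, pair, angle_deg)."""
    t = angles.groupby(["compartment", "pair"])["angle_deg"].agg(
        Mean="mean", SD=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan)
    return t.unstack("pair")
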