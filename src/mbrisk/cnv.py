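"""Copy-number feature derivation from segmented profiles.

Focal amplifications/deletions are called from SEG-style segmented
log2-ratio profiles with the rule used throughout this package: an event
is *focal* when its merged span is under 10 Mb, and *significant* when
its log2 ratio deviates from the sample's reference baseline by more
than a configurable multiple (default 4x) of the sample's median
absolute deviation (MAD).  The baseline is the probe-count-weighted
median of autosomal segment log2 ratios and the MAD is the weighted
median absolute deviation around it, without the 1.4826 normal
consistency constant — the multiplier, not the scale convention, is the
calibrated quantity.

Chromosome-level gains/losses and the arm-level 17p call use
length-weighted mean deviations with a same-side coverage requirement;
the thresholds are package configuration, not literature constants.
The whole-chromosome-aberration favorable-risk (WCA-FR) phenotype is
true when at least two of {chr7 gain, chr8 loss, chr11 loss} hold.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, CHR17_P_END, CHROM_ORDER, CHROM_SIZES, normalize_chrom

logger = logging.getLogger(__name__)

TriState = bool | None


class ChromCall(enum.StrEnum):
    GAIN = "gain"
    LOSS = "loss"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Segment:
    """One segmented interval; coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_probes: int
    log2_ratio: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.start < self.end:
            raise ValueError(f"segment start must precede end: {self}")
        if self.start < 0 or self.end > CHROM_SIZES[self.chrom]:
            raise ValueError(f"segment outside chr{self.chrom} bounds: {self}")
        if self.n_probes < 1:
            raise ValueError("segment must cover at least one probe")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    sample_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (CHROM_ORDER[s.chrom], s.start)
        )
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValueError(
                    f"overlapping segments on chr{seg.chrom} in {self.sample_id}"
                )
            prev = seg

    def on_chrom(self, chrom: str) -> list[Segment]:
        c = normalize_chrom(chrom)
        return [s for s in self.segments if s.chrom == c]


@dataclass(frozen=True)
class FocalEvent:
    chrom: str
    start: int
    end: int
    kind: str  # "amplification" | "deletion"
    log2_ratio: float

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class ChromCallSet:
    calls: dict[str, ChromCall] = field(default_factory=dict)
    arm_17p: ChromCall = ChromCall.UNKNOWN

    def __getitem__(self, chrom: str) -> ChromCall:
        return self.calls.get(normalize_chrom(chrom), ChromCall.UNKNOWN)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median; averages the boundary pair when the half-weight
    falls exactly between two values."""
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w)
    half = cw[-1] / 2.0
    i = int(np.searchsorted(cw, half))
    if np.isclose(cw[i], half) and i + 1 < v.size:
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])


def profile_baseline_and_mad(profile: SegmentProfile) -> tuple[float, float]:
    """Probe-count-weighted baseline and raw MAD of autosomal log2 ratios.

    Sex chromosomes are excluded to avoid ploidy-by-sex artifacts.
    """
    auto = [s for s in profile.segments if s.chrom in AUTOSOMES]
    if not auto:
        raise ValueError(f"profile {profile.sample_id} has no autosomal segments")
    log2 = np.array([s.log2_ratio for s in auto])
    w = np.array([s.n_probes for s in auto], dtype=float)
    baseline = _weighted_median(log2, w)
    mad = _weighted_median(np.abs(log2 - baseline), w)
    return baseline, mad


def call_focal_events(
    profile: SegmentProfile,
    mad_multiplier: float = 4.0,
    max_length_bp: int = 10_000_000,
    min_mad_floor: float = 0.01,
) -> list[FocalEvent]:
    """Call focal events: runs of adjacent same-side qualifying segments,
    merged, spanning less than ``max_length_bp``.

    A segment qualifies when |log2 - baseline| > mad_multiplier x
    max(MAD, min_mad_floor).  Adjacent qualifying segments on the same
    side are merged before the length test: segmentation may split one
    amplicon, and it is the event, not the segment, that must be focal.
    """
    baseline, mad = profile_baseline_and_mad(profile)
    threshold = mad_multiplier * max(mad, min_mad_floor)
    events: list[FocalEvent] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in profile.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in sorted(by_chrom, key=CHROM_ORDER.__getitem__):
        segs = by_chrom[chrom]
        sides = []
        for s in segs:
            dev = s.log2_ratio - baseline
            sides.append(0 if abs(dev) <= threshold else (1 if dev > 0 else -1))
        i = 0
        while i < len(segs):
            if sides[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(segs) and sides[j + 1] == sides[i]:
                j += 1
            run = segs[i : j + 1]
            span = run[-1].end - run[0].start
            if span < max_length_bp:
                w = np.array([s.n_probes for s in run], dtype=float)
                mean_log2 = float(
                    np.average([s.log2_ratio for s in run], weights=w)
                )
                events.append(
                    FocalEvent(
                        chrom=chrom,
                        start=run[0].start,
                        end=run[-1].end,
                        kind="amplification" if sides[i] > 0 else "deletion",
                        log2_ratio=mean_log2,
                    )
                )
            i = j + 1
    return events


def _interval_call(
    segs: list[Segment],
    baseline: float,
    gain_thresh: float,
    loss_thresh: float,
    min_fraction: float,
) -> ChromCall:
    lengths = np.array([s.length_bp for s in segs], dtype=float)
    dev = np.array([s.log2_ratio for s in segs]) - baseline
    mean_dev = float(np.average(dev, weights=lengths))
    total = lengths.sum()
    frac_up = lengths[dev > 0].sum() / total
    frac_down = lengths[dev < 0].sum() / total
    if mean_dev > gain_thresh and frac_up >= min_fraction:
        return ChromCall.GAIN
    if mean_dev < loss_thresh and frac_down >= min_fraction:
        return ChromCall.LOSS
    return ChromCall.NEUTRAL


def call_chromosome_aberrations(
    profile: SegmentProfile,
    gain_thresh: float = 0.1,
    loss_thresh: float = -0.1,
    min_fraction: float = 0.8,
) -> ChromCallSet:
    """Whole-chromosome gain/loss calls for every autosome plus the
    arm-level 17p call.

    A chromosome is called gain (loss) iff the length-weighted mean
    deviation from baseline exceeds ``gain_thresh`` (falls below
    ``loss_thresh``) AND at least ``min_fraction`` of covered length
    lies on the same side of the baseline.  Chromosomes absent from the
    profile are called unknown with a logged warning.
    """
    baseline, _ = profile_baseline_and_mad(profile)
    calls: dict[str, ChromCall] = {}
    for chrom in AUTOSOMES:
        segs = profile.on_chrom(chrom)
        if not segs:
            logger.warning(
                "sample %s: chromosome %s absent from profile; call unknown",
                profile.sample_id,
                chrom,
            )
            calls[chrom] = ChromCall.UNKNOWN
            continue
        calls[chrom] = _interval_call(
            segs, baseline, gain_thresh, loss_thresh, min_fraction
        )

    # Arm-level 17p: clip chr17 segments to the packaged arm boundary.
    arm_segs = []
    for s in profile.on_chrom("17"):
        if s.start < CHR17_P_END:
            arm_segs.append(
                Segment(
                    chrom="17",
                    start=s.start,
                    end=min(s.end, CHR17_P_END),
                    n_probes=s.n_probes,
                    log2_ratio=s.log2_ratio,
                )
            )
    if arm_segs:
        arm_17p = _interval_call(
            arm_segs, baseline, gain_thresh, loss_thresh, min_fraction
        )
    else:
        logger.warning(
            "sample %s: no segments on 17p; arm call unknown", profile.sample_id
        )
        arm_17p = ChromCall.UNKNOWN
    return ChromCallSet(calls=calls, arm_17p=arm_17p)


def wca_fr_from_calls(c7: ChromCall, c8: ChromCall, c11: ChromCall) -> TriState:
    """WCA-FR phenotype: at least 2 of {chr7 gain, chr8 loss, chr11 loss}.

    Unknown calls yield an unknown phenotype only when they are decisive,
    i.e. when the known calls neither reach two hits nor rule them out.
    """
    targets = [(c7, ChromCall.GAIN), (c8, ChromCall.LOSS), (c11, ChromCall.LOSS)]
    hits = sum(1 for call, want in targets if call == want)
    unknown = sum(1 for call, _ in targets if call == ChromCall.UNKNOWN)
    if hits >= 2:
        return True
    if hits + unknown < 2:
        return False
    return None


def wca_fr_phenotype(calls: ChromCallSet) -> TriState:
    return wca_fr_from_calls(calls["7"], calls["8"], calls["11"])


# ---------------------------------------------------------------------------
# SEG-dialect input/output (files are 1-based inclusive; memory is
# 0-based half-open)

SEG_COLUMNS = ["sample_id", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_seg(path) -> list[SegmentProfile]:
    """Read a SEG-like tab-delimited file into per-sample profiles."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {', '.join(missing)}")
    profiles: dict[str, list[Segment]] = {}
    for row in df.itertuples(index=False):
        vals = dict(zip(df.columns, row))
        start1 = int(vals["loc.start"])
        end1 = int(vals["loc.end"])
        profiles.setdefault(vals["sample_id"], []).append(
            Segment(
                chrom=vals["chrom"],
                start=start1 - 1,
                end=end1,
                n_probes=int(vals["num.mark"]),
                log2_ratio=float(vals["seg.mean"]),
            )
        )
    return [SegmentProfile(sample_id=sid, segments=segs) for sid, segs in profiles.items()]


def write_seg(profiles: list[SegmentProfile], path) -> None:
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "chrom": s.chrom,
                    "loc.start": s.start + 1,
                    "loc.end": s.end,
                    "num.mark": s.n_probes,
                    "seg.mean": repr(s.log2_ratio),
                }
            )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def events_to_bed(events: list[FocalEvent], path) -> None:
    """BED-like export (0-based half-open)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.kind}\t{ev.log2_ratio:.4f}\n"
            )


def phenotype_summary(profile: SegmentProfile, **call_kwargs) -> dict:
    """JSON-able per-sample phenotype summary."""
    baseline, mad = profile_baseline_and_mad(profile)
    calls = call_chromosome_aberrations(profile)
    events = call_focal_events(profile, **call_kwargs)
    wca = wca_fr_phenotype(calls)
    return {
        "sample_id": profile.sample_id,
        "baseline": baseline,
        "mad": mad,
        "chrom_calls": {c: str(v) for c, v in calls.calls.items()},
        "arm_17p": str(calls.arm_17p),
        "wca_fr": wca,
        "n_focal_events": len(events),
        "focal_events": [
            {
                "chrom": ev.chrom,
                "start": ev.start,
                "end": ev.end,
                "kind": ev.kind,
                "log2_ratio": ev.log2_ratio,
            }
            for ev in events
        ],
    }


def phenotype_summary_json(profiles: list[SegmentProfile], path, **call_kwargs) -> None:
    payload = [phenotype_summary(p, **call_kwargs) for p in profiles]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
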