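"""IUPAC promoter-motif scanning with positional enrichment statistics.

Scans 1000-nt upstream regions for degenerate consensus motifs — the
two classics of plant ribosomal-protein promoters are built in: the
site II motif ARGCCCA (a TCP transcription-factor target) around -70
and the telo-box AAACCCWA (an interstitial telomere repeat acting as an
expression enhancer) around -30.  Coordinates are 3'-anchored: the last
promoter base (just upstream of the start codon) is -1 and a hit is
placed at the offset of its first base.

Per promoter set the scanner reports occupancy (fraction of promoters
with a hit anywhere), windowed occupancy (hit starting inside the
motif's positional window) and a 50-nt binned positional histogram,
which is compared against a random-cluster background envelope of
mean +/- 2.5 SD over resampled promoter subsets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import pct, round_half_up
from .synthetic import IUPAC_CODES

__all__ = [
    "MotifPattern",
    "MotifHitProfile",
    "BackgroundEnvelope",
    "SITE_II",
    "TELO_BOX",
    "scan",
    "class_occupancy",
    "background_envelope",
    "enrichment_calls",
    "read_promoters",
]

ENVELOPE_MULTIPLIER = 2.5


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate consensus motif with its expected positional window."""

    name: str
    iupac: str
    window_center: int
    window_halfwidth: int

    def __post_init__(self) -> None:
        motif = self.iupac.upper()
        bad = [c for c in motif if c not in IUPAC_CODES]
        if bad or not motif:
            raise ValueError(f"invalid IUPAC motif {self.iupac!r} (bad codes {bad})")
        if self.window_halfwidth < 0:
            raise ValueError("window halfwidth must be >= 0")
        object.__setattr__(self, "iupac", motif)

    @property
    def window(self) -> tuple[int, int]:
        c, h = self.window_center, self.window_halfwidth
        return (c - h, c + h)


#: TCP-target site II element, expected at -70 +/- 25 from the start codon.
SITE_II = MotifPattern("site_II", "ARGCCCA", -70, 25)
#: Interstitial telomere repeat (telo-box), expected at -30 +/- 25.
TELO_BOX = MotifPattern("telo_box", "AAACCCWA", -30, 25)


@dataclass
class MotifHitProfile:
    """Hit positions and positional statistics for one promoter set."""

    motif: MotifPattern
    hits: dict[str, list[int]]  # promoter id -> 3'-anchored start offsets
    n_promoters: int
    promoter_length: int
    bin_width: int
    occupancy: float  # fraction of promoters with >= 1 hit anywhere
    windowed_occupancy: float  # ... with >= 1 hit starting inside the window
    histogram: np.ndarray  # hit counts per bin, 5' bin first

    @property
    def bin_edges(self) -> list[tuple[int, int]]:
        """Inclusive (start, end) offsets of each histogram bin."""
        L, w = self.promoter_length, self.bin_width
        return [(-L + i * w, -L + (i + 1) * w - 1) for i in range(len(self.histogram))]

    def occupancy_pct(self) -> tuple[int, int]:
        return (
            round_half_up(pct(self.occupancy * self.n_promoters, self.n_promoters)),
            round_half_up(
                pct(self.windowed_occupancy * self.n_promoters, self.n_promoters)
            ),
        )


@dataclass
class BackgroundEnvelope:
    """Random-cluster positional background: per-bin mean +/- 2.5 SD."""

    motif: MotifPattern
    mean: np.ndarray
    sd: np.ndarray
    multiplier: float
    n_resamples: int
    set_size: int
    bin_width: int
    promoter_length: int

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.multiplier * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.multiplier * self.sd


def _compile(motif: str) -> re.Pattern:
    """Overlap-aware regex for an IUPAC motif.

    A sequence N is matched only by a motif N; every other motif code
    matches exactly its base set.
    """
    parts = []
    for c in motif:
        allowed = IUPAC_CODES[c] + ("N" if c == "N" else "")
        parts.append(f"[{allowed}]" if len(allowed) > 1 else allowed)
    return re.compile(f"(?=({''.join(parts)}))")


def _normalize(seq: str, promoter_length: int) -> str:
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"promoter sequence contains non-nucleotide codes {sorted(bad)}")
    return s[-promoter_length:]  # keep the 1000 nt next to the start codon


def _as_records(promoters) -> list[tuple[str, str]]:
    records = []
    for item in promoters:
        if isinstance(item, tuple):
            records.append((item[0], str(item[1])))
        else:  # Bio.SeqRecord
            records.append((item.id, str(item.seq)))
    return records


def read_promoters(path) -> list[tuple[str, str]]:
    """Read promoters from FASTA; gene id = first token of the header."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def scan(
    promoters: Iterable,
    motif: MotifPattern,
    promoter_length: int = 1000,
    bin_width: int = 50,
) -> MotifHitProfile:
    """All forward-strand matches of ``motif`` in each promoter.

    Sequences longer than ``promoter_length`` are first truncated to
    their 3'-most ``promoter_length`` bases.  Overlapping matches all
    count in the histogram; occupancy is a per-promoter indicator so
    multiplicity cannot inflate it.  Window membership uses the hit's
    start offset, boundary inclusive.
    """
    records = _as_records(promoters)
    if not records:
        raise ValueError("empty promoter set")
    pattern = _compile(motif.iupac)
    lo, hi = motif.window
    n_bins = int(np.ceil(promoter_length / bin_width))
    hist = np.zeros(n_bins, dtype=np.int64)
    hits: dict[str, list[int]] = {}
    n_occ = 0
    n_win = 0
    for pid, seq in records:
        s = _normalize(seq, promoter_length)
        L = len(s)
        offs = [m.start() - L for m in pattern.finditer(s)]
        hits[pid] = offs
        if offs:
            n_occ += 1
            if any(lo <= o <= hi for o in offs):
                n_win += 1
            for o in offs:
                hist[(o + promoter_length) // bin_width] += 1
    n = len(records)
    return MotifHitProfile(
        motif=motif,
        hits=hits,
        n_promoters=n,
        promoter_length=promoter_length,
        bin_width=bin_width,
        occupancy=n_occ / n,
        windowed_occupancy=n_win / n,
        histogram=hist,
    )


def class_occupancy(profiles: Mapping[object, MotifHitProfile]) -> pd.DataFrame:
    """Occupancy table over promoter classes.

    One row per (class, motif): percentage of promoters with a hit
    anywhere and with a hit in the motif's positional window, half-up
    rounded, with the denominators attached.
    """
    if not profiles:
        raise ValueError("need at least one class profile")
    rows = []
    for label, prof in profiles.items():
        occ, win = prof.occupancy_pct()
        rows.append(
            {
                "class": label,
                "motif": prof.motif.name,
                "occupancy_pct": occ,
                "windowed_pct": win,
                "n_promoters": prof.n_promoters,
            }
        )
    return pd.DataFrame(rows)


def background_envelope(
    promoter_pool: Iterable,
    motif: MotifPattern,
    set_size: int,
    n_resamples: int = 1000,
    seed: int = 0,
    promoter_length: int = 1000,
    bin_width: int = 50,
) -> BackgroundEnvelope:
    """Positional background from random promoter clusters.

    Draws ``n_resamples`` subsets of ``set_size`` promoters without
    replacement from the pool, bins each subset's hit positions and
    summarizes per-bin counts as mean +/- 2.5 SD.  Each pool promoter
    is scanned once; resampling only re-aggregates.
    """
    records = _as_records(promoter_pool)
    if set_size > len(records):
        raise ValueError(
            f"pool of {len(records)} promoters smaller than set_size {set_size}"
        )
    pattern = _compile(motif.iupac)
    n_bins = int(np.ceil(promoter_length / bin_width))
    per_promoter = np.zeros((len(records), n_bins), dtype=np.int64)
    for i, (_, seq) in enumerate(records):
        s = _normalize(seq, promoter_length)
        L = len(s)
        for m in pattern.finditer(s):
            per_promoter[i, (m.start() - L + promoter_length) // bin_width] += 1
    rng = np.random.default_rng(seed)
    sums = np.empty((n_resamples, n_bins))
    for r in range(n_resamples):
        idx = rng.choice(len(records), size=set_size, replace=False)
        sums[r] = per_promoter[idx].sum(axis=0)
    return BackgroundEnvelope(
        motif=motif,
        mean=sums.mean(axis=0),
        sd=sums.std(axis=0),
        multiplier=ENVELOPE_MULTIPLIER,
        n_resamples=n_resamples,
        set_size=set_size,
        bin_width=bin_width,
        promoter_length=promoter_length,
    )


def enrichment_calls(
    profile: MotifHitProfile, env: BackgroundEnvelope
) -> list[str]:
    """Per-bin flags comparing a class histogram with the background envelope.

    The class histogram is rescaled to the envelope's set size before
    the comparison; a bin is "above" when the scaled count exceeds
    mean + 2.5 SD, "below" when under mean - 2.5 SD, otherwise "within".
    """
    if (
        profile.bin_width != env.bin_width
        or profile.promoter_length != env.promoter_length
        or len(profile.histogram) != len(env.mean)
    ):
        raise ValueError("profile and envelope use different binnings")
    scaled = profile.histogram * (env.set_size / profile.n_promoters)
    flags = []
    for value, lo, hi in zip(scaled, env.lower, env.upper):
        if value > hi:
            flags.append("above")
        elif value < lo:
            flags.append("below")
        else:
            flags.append("within")
    return flags


def envelope_table(
    profile: MotifHitProfile, env: BackgroundEnvelope
) -> pd.DataFrame:
    """Long-format per-bin export: class histogram, envelope, flag."""
    flags = enrichment_calls(profile, env)
    edges = profile.bin_edges
    return pd.DataFrame(
        {
            "bin_start": [e[0] for e in edges],
            "bin_end": [e[1] for e in edges],
            "class_count": profile.histogram,
            "scaled_count": profile.histogram * (env.set_size / profile.n_promoters),
            "bg_mean": env.mean,
            "bg_sd": env.sd,
            "flag": flags,
        }
    )
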