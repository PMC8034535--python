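"""Test-interval construction: fixed flanks, LD-based boundaries with
hotspot extension, or user-supplied intervals.

Internal coordinates are 1-based inclusive; BED I/O converts to/from
0-based half-open at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .runlog import RunLog

#: Hard input limits.
MAX_FLANK_BP = 10_000_000
MAX_INTERVAL_BP = 20_000_000
MAX_INPUT_COUNT = 10_000

#: Half-width of the LD window centred on an index variant (1 Mbp total).
LD_WINDOW_HALF_BP = 500_000

#: Default recombination-rate threshold (cM/Mb) a map entry must strictly
#: exceed to act as a hotspot boundary.
DEFAULT_HOTSPOT_RATE = 3.0

LD_STATS = ("r2", "dprime")
POPULATIONS = ("CEU", "EUR", "EAS", "SAS", "AFR", "AMR")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    label: str = ""
    origin: str = "user"

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"interval {self.label or self.region_string()}: "
                f"need 1 <= start <= end, got {self.start}-{self.end}",
                code="bad_coordinates",
            )
        if not self.label:
            object.__setattr__(self, "label", self.region_string())

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def region_string(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class LDProxy:
    variant_id: str
    chrom: str
    pos: int
    r2: float
    dprime: float


@dataclass
class LDProxyTable:
    """Proxies around one index variant, restricted to the 1 Mbp LD window."""

    index_variant_id: str
    chrom: str
    index_pos: int
    proxies: list  # of LDProxy

    def __post_init__(self):
        for p in self.proxies:
            if abs(p.pos - self.index_pos) > LD_WINDOW_HALF_BP:
                raise ValidationError(
                    f"proxy {p.variant_id} at {p.pos} lies outside the "
                    f"{2 * LD_WINDOW_HALF_BP / 1e6:g} Mbp window around "
                    f"{self.index_variant_id}",
                    code="proxy_outside_window",
                )
        if not any(
            p.variant_id == self.index_variant_id and p.pos == self.index_pos
            for p in self.proxies
        ):
            self.proxies.insert(
                0,
                LDProxy(self.index_variant_id, self.chrom, self.index_pos, 1.0, 1.0),
            )


class LDSource:
    """Directory-backed LD proxy source: one tab file per index variant.

    The population label selects a subdirectory when present. Proxies
    outside the 1 Mbp window are dropped with a warning (they are never
    admitted into interval construction).
    """

    def __init__(self, directory, population: str | None = None, log: RunLog | None = None):
        base = Path(directory)
        if population and (base / population).is_dir():
            base = base / population
        self.directory = base
        self.log = log if log is not None else RunLog()

    def get(self, variant_id: str, chrom: str, index_pos: int) -> LDProxyTable | None:
        path = self.directory / f"{variant_id}.tsv"
        if not path.exists():
            self.log.warn(
                f"no LD table for {variant_id}; degrading to 1-bp interval",
                count_key="missing_ld_tables",
            )
            return None
        return read_ld_table(path, variant_id, chrom, index_pos, log=self.log)

    def position_of(self, variant_id: str) -> tuple[str, int] | None:
        """Resolve an rsID to its position via its own proxy table."""
        path = self.directory / f"{variant_id}.tsv"
        if not path.exists():
            return None
        df = pd.read_csv(path, sep="\t", dtype=str)
        hit = df[df["variant_id"] == variant_id]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return str(row["chrom"]), int(row["pos"])


def read_ld_table(
    path, index_variant_id: str, chrom: str, index_pos: int, log: RunLog | None = None
) -> LDProxyTable:
    log = log if log is not None else RunLog()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "chrom", "pos", "r2", "dprime"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: LD table missing columns {sorted(missing)}", code="bad_table"
        )
    proxies = []
    for row in df.itertuples(index=False):
        pos = int(row.pos)
        if abs(pos - index_pos) > LD_WINDOW_HALF_BP:
            log.warn(
                f"{path}: proxy {row.variant_id} at {pos} outside the "
                f"1 Mbp window; dropped",
                count_key="proxies_outside_window",
            )
            continue
        proxies.append(
            LDProxy(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=pos,
                r2=float(row.r2),
                dprime=float(row.dprime),
            )
        )
    return LDProxyTable(
        index_variant_id=index_variant_id,
        chrom=chrom,
        index_pos=index_pos,
        proxies=proxies,
    )


@dataclass
class RecombinationMap:
    """Per-chromosome sorted (pos, rate cM/Mb) arrays."""

    positions: dict  # chrom -> np.ndarray of int positions, strictly increasing
    rates: dict  # chrom -> np.ndarray of float rates

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            rates = np.asarray(self.rates[chrom], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"recombination map {chrom}: positions not strictly increasing",
                    code="bad_recomb_map",
                )
            if np.any(rates < 0):
                raise ValidationError(
                    f"recombination map {chrom}: negative rates", code="bad_recomb_map"
                )
            self.positions[chrom] = pos
            self.rates[chrom] = rates


def read_recomb_map(path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "rate_cM_per_Mb"}
    if missing := required - set(df.columns):
        raise ValidationError(
            f"{path}: recombination map missing columns {sorted(missing)}",
            code="bad_table",
        )
    positions, rates = {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        positions[chrom] = grp["pos"].to_numpy(dtype=np.int64)
        rates[chrom] = grp["rate_cM_per_Mb"].to_numpy(dtype=float)
    return RecombinationMap(positions=positions, rates=rates)


def make_flank_intervals(
    positions: Sequence[tuple[str, int, str]],
    flank_left: int,
    flank_right: int,
    chrom_sizes: dict,
    log: RunLog | None = None,
) -> list:
    """Fixed flanks around input positions, clipped to chromosome bounds."""
    log = log if log is not None else RunLog()
    for flank, side in ((flank_left, "left"), (flank_right, "right")):
        if not 0 <= flank <= MAX_FLANK_BP:
            raise ValidationError(
                f"{side} flank {flank} bp outside [0, {MAX_FLANK_BP}]",
                code="flank_too_large",
            )
    out = []
    for chrom, pos, label in positions:
        size = chrom_sizes.get(chrom)
        if size is None:
            raise DataError(
                f"position {label}: unknown chromosome {chrom}", code="unknown_chrom"
            )
        if not 1 <= pos <= size:
            raise ValidationError(
                f"position {label}: {chrom}:{pos} outside chromosome (size {size})",
                code="position_outside_chrom",
            )
        start = max(1, pos - flank_left)
        end = min(size, pos + flank_right)
        if start == 1 and pos - flank_left < 1:
            log.note(f"{label}: interval start clipped to chromosome start")
        if end == size and pos + flank_right > size:
            log.note(f"{label}: interval end clipped to chromosome end")
        out.append(GenomicInterval(chrom, start, end, label=label, origin="flank"))
    return out


def make_ld_interval(
    index: tuple[str, int, str],
    ld: LDProxyTable | None,
    stat: str = "r2",
    threshold: float = 0.8,
    log: RunLog | None = None,
) -> GenomicInterval:
    """Span of the most distant proxies meeting the LD threshold.

    The index variant always qualifies, so the interval always contains its
    position. A missing/empty proxy table degrades to a 1-bp interval.
    """
    log = log if log is not None else RunLog()
    chrom, pos, label = index
    if stat not in LD_STATS:
        raise ValidationError(f"LD stat must be one of {LD_STATS}", code="bad_ld_stat")
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(
            f"LD threshold {threshold} outside [0, 1]", code="bad_ld_threshold"
        )
    if ld is None or not ld.proxies:
        log.warn(
            f"{label}: no LD proxies available; using 1-bp interval",
            count_key="ld_fallback_intervals",
        )
        return GenomicInterval(chrom, pos, pos, label=label, origin="ld")
    if ld.index_pos != pos or ld.chrom != chrom:
        raise DataError(
            f"{label}: LD table indexed at {ld.chrom}:{ld.index_pos}, "
            f"input is {chrom}:{pos}",
            code="ld_index_mismatch",
        )
    qualifying = [
        p.pos for p in ld.proxies if getattr(p, stat) >= threshold
    ]
    qualifying.append(pos)  # index always qualifies
    return GenomicInterval(
        chrom, min(qualifying), max(qualifying), label=label, origin="ld"
    )


def extend_to_hotspot(
    interval: GenomicInterval,
    recomb_map: RecombinationMap,
    rate_threshold: float = DEFAULT_HOTSPOT_RATE,
) -> GenomicInterval:
    """Extend boundaries to the nearest map entries with rate strictly above
    the threshold (left entry at or left of start, right entry at or right of
    end); unchanged on a side with no qualifying entry. Idempotent.
    """
    pos = recomb_map.positions.get(interval.chrom)
    if pos is None:
        raise DataError(
            f"recombination map does not cover chromosome {interval.chrom}",
            code="unknown_chrom",
        )
    rates = recomb_map.rates[interval.chrom]
    hot = rates > rate_threshold

    new_start, new_end = interval.start, interval.end
    left = np.nonzero(hot & (pos <= interval.start))[0]
    if left.size:
        new_start = int(pos[left[-1]])
    right = np.nonzero(hot & (pos >= interval.end))[0]
    if right.size:
        new_end = int(pos[right[0]])
    if (new_start, new_end) == (interval.start, interval.end):
        return interval
    return replace(interval, start=new_start, end=new_end)


def validate_intervals(
    intervals: list,
    max_count: int = MAX_INPUT_COUNT,
    max_length: int = MAX_INTERVAL_BP,
) -> list:
    """Enforce the input-count and interval-size limits; pass-through on success."""
    if len(intervals) > max_count:
        raise ValidationError(
            f"{len(intervals)} intervals exceed the maximum input of {max_count}",
            code="too_many_intervals",
        )
    for i, iv in enumerate(intervals, start=1):
        if iv.length > max_length:
            raise ValidationError(
                f"interval #{i} ({iv.label}) is {iv.length} bp, over the "
                f"{max_length} bp maximum",
                code="interval_too_long",
            )
    return intervals


# ---------------------------------------------------------------------------
# I/O

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_positions_file(path, ld_source: LDSource | None = None) -> list:
    """3-column (chrom, pos, label) text, or a bare rsID list resolved via
    the LD source tables. Returns (chrom, pos, label) tuples."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) >= 2:
                chrom, pos = fields[0], fields[1]
                label = fields[2] if len(fields) >= 3 else f"{chrom}:{pos}"
                try:
                    pos = int(pos)
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: position {pos!r} is not an integer",
                        code="bad_coordinates",
                    ) from None
                out.append((chrom, pos, label))
            else:
                rsid = fields[0]
                if ld_source is None:
                    raise ValidationError(
                        f"{path}:{lineno}: bare variant id {rsid} requires an LD source "
                        "to resolve its position",
                        code="unresolvable_rsid",
                    )
                resolved = ld_source.position_of(rsid)
                if resolved is None:
                    raise DataError(
                        f"{path}:{lineno}: variant id {rsid} not found in LD source",
                        code="unresolvable_rsid",
                    )
                out.append((resolved[0], resolved[1], rsid))
    return out


def read_intervals_file(path) -> list:
    """BED3(+label) or ``chrom:start-end`` lines -> GenomicInterval list."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            m = _REGION_RE.match(line)
            try:
                if m:
                    iv = GenomicInterval(
                        m["chrom"], int(m["start"]), int(m["end"]), origin="user"
                    )
                else:
                    fields = line.split("\t") if "\t" in line else line.split()
                    if len(fields) < 3:
                        raise ValidationError(
                            f"{path}:{lineno}: expected BED3 or chrom:start-end",
                            code="bad_coordinates",
                        )
                    chrom, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    iv = GenomicInterval(
                        chrom, bed_start + 1, bed_end, label=label, origin="user"
                    )
            except (ValueError, ValidationError) as exc:
                code = getattr(exc, "code", "bad_coordinates")
                raise ValidationError(
                    f"{path}:{lineno}: malformed interval ({exc})", code=code
                ) from None
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Echo intervals as BED (0-based half-open), bit-exact round trip."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"], df["size"].astype(int)))
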