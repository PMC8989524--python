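"""Genome layout, gene models, binned signal tracks and Poisson binarization.

All coordinates are 0-based, half-open internally.  GFF3 input (1-based,
inclusive) is converted on read.  Signal is binned at a fixed resolution
(default 200 bp) by the 5' start coordinate of each read interval; binary
presence/absence calls per mark are made with a Poisson upper-tail test
against a control-derived (or global-mean) background, and the per-mark
columns assemble into the binary observation matrix consumed by the HMM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

REGION_CLASSES = ("AUTOSOME", "PAR", "SDR_FEMALE", "SDR_MALE")

DEFAULT_BIN_SIZE = 200
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_LAMBDA_FLOOR = 1.0
DEFAULT_RATIO_CAP = 50.0


class LayoutError(ValueError):
    """Raised for invalid genome layouts or layout/track mismatches."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    """Chromosome lengths plus a partition into region classes.

    ``regions`` is a DataFrame with columns (chromosome, start, end,
    region_class); every base of every chromosome belongs to exactly one
    region class, AUTOSOME being the default fill.
    """

    chromosomes: dict[str, int]
    regions: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise LayoutError(f"chromosome {name!r} has non-positive length {length}")
        declared = self.regions
        if declared is None:
            declared = pd.DataFrame(columns=["chromosome", "start", "end", "region_class"])
        self.regions = _fill_autosome(self.chromosomes, declared)

    @property
    def chromosome_names(self) -> list[str]:
        return list(self.chromosomes)

    def n_bins(self, bin_size: int = DEFAULT_BIN_SIZE) -> dict[str, int]:
        return {c: math.ceil(l / bin_size) for c, l in self.chromosomes.items()}

    def total_bins(self, bin_size: int = DEFAULT_BIN_SIZE) -> int:
        return sum(self.n_bins(bin_size).values())

    def region_class_at(self, chromosome: str, position: int) -> str:
        """Region class of a single base position (used for gene midpoints)."""
        sub = self.regions[self.regions["chromosome"] == chromosome]
        hit = sub[(sub["start"] <= position) & (position < sub["end"])]
        if hit.empty:
            raise LayoutError(f"position {chromosome}:{position} outside layout")
        return hit.iloc[0]["region_class"]

    def region_spans(self) -> pd.DataFrame:
        """Analysis regions: one row per chromosome (whole span) for autosomes,
        and separate PAR / SDR rows on the sex chromosome."""
        rows = []
        special = self.regions[self.regions["region_class"] != "AUTOSOME"]
        special_chroms = set(special["chromosome"])
        for chrom, length in self.chromosomes.items():
            if chrom not in special_chroms:
                rows.append((chrom, chrom, 0, length, "AUTOSOME"))
        for _, r in special.iterrows():
            label = f"{r.chromosome}:{r.region_class}"
            rows.append((label, r.chromosome, int(r.start), int(r.end), r.region_class))
        return pd.DataFrame(rows, columns=["region", "chromosome", "start", "end", "region_class"])


def _fill_autosome(chromosomes: dict[str, int], declared: pd.DataFrame) -> pd.DataFrame:
    declared = declared.copy()
    if len(declared):
        bad = set(declared["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise LayoutError(f"unknown region classes: {sorted(bad)}")
    rows = []
    for chrom, length in chromosomes.items():
        sub = declared[declared["chromosome"] == chrom].sort_values("start")
        cursor = 0
        prev = None
        for _, r in sub.iterrows():
            s, e = int(r.start), int(r.end)
            if s < 0 or e > length or s >= e:
                raise LayoutError(
                    f"region {chrom}:{s}-{e} ({r.region_class}) outside chromosome "
                    f"of length {length}")
            if s < cursor:
                raise LayoutError(
                    f"overlapping regions on {chrom}: {prev} and "
                    f"{chrom}:{s}-{e} ({r.region_class})")
            if s > cursor:
                rows.append((chrom, cursor, s, "AUTOSOME"))
            rows.append((chrom, s, e, r.region_class))
            cursor = e
            prev = f"{chrom}:{s}-{e} ({r.region_class})"
        if cursor < length:
            rows.append((chrom, cursor, length, "AUTOSOME"))
    unknown = set(declared["chromosome"]) - set(chromosomes)
    if unknown:
        raise LayoutError(f"regions on unknown chromosomes: {sorted(unknown)}")
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "region_class"])


def load_genome_layout(path) -> GenomeLayout:
    """Read a layout config (YAML: ``chromosomes`` map + optional ``regions`` list)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    chromosomes = {str(k): int(v) for k, v in doc["chromosomes"].items()}
    regions = doc.get("regions") or []
    reg = pd.DataFrame(
        [(str(r["chromosome"]), int(r["start"]), int(r["end"]),
          str(r.get("class", r.get("region_class")))) for r in regions],
        columns=["chromosome", "start", "end", "region_class"],
    )
    return GenomeLayout(chromosomes=chromosomes, regions=reg)


def write_genome_layout(layout: GenomeLayout, path) -> None:
    doc = {
        "chromosomes": dict(layout.chromosomes),
        "regions": [
            {"chromosome": r.chromosome, "start": int(r.start), "end": int(r.end),
             "class": r.region_class}
            for _, r in layout.regions.iterrows() if r.region_class != "AUTOSOME"
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    region_class: str = "AUTOSOME"
    te_overlap: bool = False
    age_class: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _parse_gff3_genes(path) -> list[tuple[str, str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"gene line without ID attribute: {line.strip()}")
            # GFF3 is 1-based inclusive -> 0-based half-open
            out.append((gid, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]))
    return out


def _parse_bed_genes(path) -> list[tuple[str, str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            gid = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            out.append((gid, chrom, start, end, strand))
    return out


def load_gene_models(
    path,
    layout: GenomeLayout,
    te_table: pd.DataFrame | None = None,
    age_table: pd.DataFrame | None = None,
) -> list[GeneModel]:
    """Load genes from GFF3 (``gene`` features) or BED.

    Region class is assigned by the gene midpoint against the layout.
    ``te_table`` (gene_id, te_overlap) and ``age_table`` (gene_id, age_class)
    are optional side tables.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        raw = _parse_gff3_genes(path)
    else:
        raw = _parse_bed_genes(path)
    te_map = {}
    if te_table is not None:
        te_map = dict(zip(te_table["gene_id"], te_table["te_overlap"].astype(bool)))
    age_map = {}
    if age_table is not None:
        age_map = dict(zip(age_table["gene_id"], age_table["age_class"]))
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for gid, chrom, start, end, strand in raw:
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r}")
        seen.add(gid)
        if chrom not in layout.chromosomes:
            raise LayoutError(f"gene {gid} on unknown chromosome {chrom!r}")
        if start < 0 or end > layout.chromosomes[chrom]:
            raise LayoutError(f"gene {gid} outside chromosome {chrom} bounds")
        mid = (start + end) // 2
        genes.append(GeneModel(
            gene_id=gid, chromosome=chrom, start=start, end=end, strand=strand,
            region_class=layout.region_class_at(chrom, mid),
            te_overlap=bool(te_map.get(gid, False)),
            age_class=str(age_map.get(gid, "UNKNOWN")),
        ))
    return genes


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.chromosome, g.start, g.end, g.strand, g.region_class,
          g.te_overlap, g.age_class) for g in genes],
        columns=["gene_id", "chromosome", "start", "end", "strand",
                 "region_class", "te_overlap", "age_class"],
    )


# ---------------------------------------------------------------------------
# Binned tracks
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """Per-chromosome per-bin signal (read counts or coverage ratios)."""

    bin_size: int
    values: dict[str, np.ndarray]
    mark: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"track {self.mark}/{chrom}: values must be finite and >= 0")
            self.values[chrom] = v

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def concat(self, order: list[str] | None = None) -> np.ndarray:
        order = order if order is not None else list(self.values)
        return np.concatenate([self.values[c] for c in order])

    def same_shape_as(self, other: "BinnedTrack") -> bool:
        return (self.bin_size == other.bin_size
                and set(self.values) == set(other.values)
                and all(len(self.values[c]) == len(other.values[c]) for c in self.values))


def bin_signal(
    intervals: pd.DataFrame,
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    mark: str = "",
    sample: str = "",
) -> BinnedTrack:
    """Count read intervals per fixed-size bin, assigning each read to the bin
    containing its 5' start coordinate.  ``intervals`` needs columns
    (chromosome, start); a trailing partial bin is included.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    nb = layout.n_bins(bin_size)
    values = {c: np.zeros(n, dtype=float) for c, n in nb.items()}
    if len(intervals):
        unknown = set(intervals["chromosome"].unique()) - set(layout.chromosomes)
        if unknown:
            raise LayoutError(f"intervals on unknown chromosomes: {sorted(unknown)}")
        for chrom, sub in intervals.groupby("chromosome", observed=True):
            idx = (sub["start"].to_numpy(dtype=np.int64) // bin_size)
            if np.any(idx < 0) or np.any(idx >= nb[chrom]):
                raise LayoutError(f"interval start outside {chrom} bounds")
            values[chrom] += np.bincount(idx, minlength=nb[chrom]).astype(float)
    return BinnedTrack(bin_size=bin_size, values=values, mark=mark, sample=sample)


def load_bedgraph_track(
    path,
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    mark: str = "",
    sample: str = "",
) -> BinnedTrack:
    """Read a bedGraph coverage track into per-bin mean coverage.

    Each interval's value is spread over the bins it overlaps, weighted by
    the overlapped base count, then divided by the bin width — so a constant
    bedGraph yields that constant in every bin.
    """
    nb = layout.n_bins(bin_size)
    values = {c: np.zeros(n, dtype=float) for c, n in nb.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chromosome", "start", "end", "value"])
    unknown = set(df["chromosome"].unique()) - set(layout.chromosomes)
    if unknown:
        raise LayoutError(f"bedGraph intervals on unknown chromosomes: {sorted(unknown)}")
    for r in df.itertuples():
        b0 = int(r.start) // bin_size
        b1 = (int(r.end) - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(int(r.start), b * bin_size)
            hi = min(int(r.end), (b + 1) * bin_size)
            values[r.chromosome][b] += r.value * (hi - lo) / bin_size
    return BinnedTrack(bin_size=bin_size, values=values, mark=mark, sample=sample)


# ---------------------------------------------------------------------------
# SES normalization (display-scale ratio tracks)
# ---------------------------------------------------------------------------

def ses_normalize(
    ip: BinnedTrack,
    control: BinnedTrack,
    ratio_cap: float = DEFAULT_RATIO_CAP,
) -> tuple[BinnedTrack, float]:
    """Signal-extraction scaling of an IP track against a control.

    Bins are ranked by ascending IP signal; the scaling point k* maximizes the
    gap between cumulative control fraction and cumulative IP fraction, and the
    scale factor is the IP/control ratio over bins ranked <= k*.  The returned
    ratio track is IP / (scale * control), with 0/0 -> 0 and positive/0 capped.
    """
    if not ip.same_shape_as(control):
        raise LayoutError("IP and control tracks have mismatched layout or bin size")
    order = list(ip.values)
    ip_all = ip.concat(order)
    ctl_all = control.concat(order)
    ctl_total = ctl_all.sum()
    if ctl_total <= 0:
        raise ValueError("control track is all zero")
    ip_total = ip_all.sum()
    rank = np.argsort(ip_all, kind="stable")
    cum_ip = np.cumsum(ip_all[rank])
    cum_ctl = np.cumsum(ctl_all[rank])
    gap = cum_ctl / ctl_total - (cum_ip / ip_total if ip_total > 0 else 0.0)
    k_star = int(np.argmax(gap))
    if gap[k_star] <= 1e-12:
        # no enrichment signal: background is the whole track
        scale = float(ip_total / ctl_total)
    else:
        ip_bg = cum_ip[k_star]
        ctl_bg = cum_ctl[k_star]
        scale = float(ip_bg / ctl_bg) if ctl_bg > 0 else float(ip_total / ctl_total)
        if scale <= 0:
            scale = float(ip_total / ctl_total)
    ratio_values = {}
    for chrom in order:
        num = ip.values[chrom]
        den = scale * control.values[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                         np.where(num > 0, ratio_cap, 0.0))
        ratio_values[chrom] = np.minimum(r, ratio_cap)
    track = BinnedTrack(bin_size=ip.bin_size, values=ratio_values,
                        mark=ip.mark, sample=ip.sample)
    return track, scale


# ---------------------------------------------------------------------------
# Poisson binarization
# ---------------------------------------------------------------------------

def _running_mean(v: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with edge windows normalized by actual coverage."""
    if window <= 1:
        return v
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def binarize(
    ip: BinnedTrack,
    control: BinnedTrack | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lambda_floor: float = DEFAULT_LAMBDA_FLOOR,
    control_scaling: str = "ses",
    control_smooth_bins: int = 11,
) -> dict[str, np.ndarray]:
    """Per-bin presence/absence call for one mark.

    The expected background per bin is the (locally smoothed) control count
    scaled to the IP's background level when a control is supplied, else the
    global mean IP per bin; a bin is called present iff the Poisson upper-tail
    probability P(X >= observed | lambda) <= ``p_threshold``.  lambda is floored
    (default 1) so zero-background bins cannot produce degenerate calls.

    ``control_scaling='ses'`` (default) scales the control with the
    signal-extraction-scaling background factor, which estimates the IP's
    background read rate from its least-enriched bins; ``'total'`` uses the
    raw sequencing-depth ratio (total IP / total control), which overstates
    the background whenever enriched regions hold a large share of IP reads.
    ``control_smooth_bins`` is the centered running-mean window applied to the
    control before scaling (1 disables smoothing).
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    if control is not None and not ip.same_shape_as(control):
        raise LayoutError("IP and control tracks have mismatched layout or bin size")
    n_total = sum(len(v) for v in ip.values.values())
    ip_total = ip.total()
    if control is not None:
        ctl_total = control.total()
        if ctl_total <= 0:
            raise ValueError("control track is all zero")
        if control_scaling == "ses":
            _, depth_ratio = ses_normalize(ip, control)
        elif control_scaling == "total":
            depth_ratio = ip_total / ctl_total
        else:
            raise ValueError(f"unknown control_scaling {control_scaling!r}")
    calls: dict[str, np.ndarray] = {}
    for chrom, obs in ip.values.items():
        if control is not None:
            lam = _running_mean(control.values[chrom], control_smooth_bins) * depth_ratio
        else:
            lam = np.full_like(obs, ip_total / n_total if n_total else 0.0)
        lam = np.maximum(lam, lambda_floor)
        # P(X >= k | lam) = sf(k - 1); observed counts are integers >= 0
        tail = sps.poisson.sf(np.round(obs) - 1, lam)
        calls[chrom] = (tail <= p_threshold).astype(np.uint8)
    return calls


# ---------------------------------------------------------------------------
# Binary observation matrix
# ---------------------------------------------------------------------------

@dataclass
class BinaryMatrix:
    """Bins x marks {0,1} observation matrix, stored per chromosome."""

    marks: list[str]
    data: dict[str, np.ndarray]  # chrom -> (n_bins, M) uint8
    bin_size: int = DEFAULT_BIN_SIZE
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom, m in self.data.items():
            m = np.asarray(m)
            if m.ndim != 2 or m.shape[1] != len(self.marks):
                raise ValueError(f"{chrom}: matrix shape {m.shape} != (*, {len(self.marks)})")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{chrom}: binary matrix entries must be 0/1")
            self.data[chrom] = m.astype(np.uint8)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    def total_bins(self) -> int:
        return sum(m.shape[0] for m in self.data.values())

    def sequences(self) -> list[np.ndarray]:
        """Per-chromosome observation sequences, in chromosome order."""
        return [self.data[c] for c in self.data]


def assemble_binary_matrix(
    columns: dict[str, dict[str, np.ndarray]],
    bin_size: int = DEFAULT_BIN_SIZE,
    sample: str = "",
    mark_order: list[str] | None = None,
) -> BinaryMatrix:
    """Stack per-mark binary columns (mark -> chrom -> 0/1 vector)."""
    marks = mark_order if mark_order is not None else sorted(columns)
    chroms = list(next(iter(columns.values())))
    data = {
        chrom: np.column_stack([columns[m][chrom] for m in marks]).astype(np.uint8)
        for chrom in chroms
    }
    return BinaryMatrix(marks=marks, data=data, bin_size=bin_size, sample=sample)


def combine_replicates(
    replicate_calls: list[dict[str, np.ndarray]],
    rule: str = "OR",
) -> dict[str, np.ndarray]:
    """Combine per-replicate binary columns per bin (rule: OR | AND)."""
    if not replicate_calls:
        raise ValueError("no replicates to combine")
    op = np.maximum if rule.upper() == "OR" else np.minimum
    if rule.upper() not in {"OR", "AND"}:
        raise ValueError(f"unknown replicate combination rule {rule!r}")
    out = {c: v.copy() for c, v in replicate_calls[0].items()}
    for rep in replicate_calls[1:]:
        for chrom in out:
            out[chrom] = op(out[chrom], rep[chrom])
    return out


# ---------------------------------------------------------------------------
# Segmentation BED dialect
# ---------------------------------------------------------------------------

_STATE_RE = __import__("re").compile(r"^E(\d+)$")


def write_segmentation(seg, path) -> None:
    """Write a segmentation as 4-column BED (chrom, start, end, E<k>),
    merging adjacent same-state tiles."""
    with open(path, "w") as fh:
        for chrom in seg.tiles["chromosome"].unique():
            sub = seg.tiles[seg.tiles["chromosome"] == chrom].sort_values("start")
            cur = None
            for _, r in sub.iterrows():
                if cur is not None and r.state == cur[2] and r.start == cur[1]:
                    cur = (cur[0], int(r.end), cur[2])
                else:
                    if cur is not None:
                        fh.write(f"{chrom}\t{cur[0]}\t{cur[1]}\t{cur[2]}\n")
                    cur = (int(r.start), int(r.end), r.state)
            if cur is not None:
                fh.write(f"{chrom}\t{cur[0]}\t{cur[1]}\t{cur[2]}\n")


def read_segmentation(path, bin_size: int = DEFAULT_BIN_SIZE, sample: str = ""):
    """Read a 4-column segmentation BED; intervals must be bin-aligned
    (trailing partial bins allowed at chromosome ends)."""
    from chromsig.hmm import Segmentation

    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, state = line.split()[:4]
            start, end = int(start), int(end)
            if not _STATE_RE.match(state):
                raise ValueError(f"{path}:{ln}: unknown state label {state!r}")
            if start % bin_size != 0:
                raise ValueError(f"{path}:{ln}: interval not bin-aligned (start {start})")
            rows.append((chrom, start, end, state))
    tiles = pd.DataFrame(rows, columns=["chromosome", "start", "end", "state"])
    return Segmentation(tiles=tiles, bin_size=bin_size, sample=sample)


# ---------------------------------------------------------------------------
# TSV helpers (all writers: tab-separated, newline-terminated, with header)
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
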