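"""Genomic coverage tracks -> fixed-window tensors, and region export.

Per-sample coverage (bedGraph-like interval + value records) is averaged
over fixed-width windows (default 25 kb) tiling each chromosome; a sample
manifest (omics group x tissue x replicate per file) then assembles the
per-sample window vectors into a 4-mode tensor ready for TD-FE.  Selected
windows are exported as BED6, and protein-coding genes overlapping them can
be counted against a local GTF/GFF3 annotation.

Coordinates are 0-based half-open (BED convention) throughout; GTF/GFF3
input is converted on read.  Strand is ignored (coverage is unstranded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .tensor import OmicsTensor

__all__ = [
    "GenomicWindows",
    "SampleManifest",
    "read_bedgraph",
    "read_chrom_sizes",
    "bin_signal",
    "assemble_tensor",
    "export_regions",
    "read_regions",
    "count_genes_in_regions",
]

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 25_000


@dataclass
class GenomicWindows:
    """Fixed-width genome tiles with one mean-signal value per window.

    ``frame`` has columns chrom, start, end (0-based half-open); windows
    tile each chromosome left to right without overlap, the last one
    truncated at the chromosome end.  ``values`` is the per-window
    length-weighted mean signal (uncovered bases count as 0 by default).
    """

    frame: pd.DataFrame
    values: np.ndarray
    width: int = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frame) != len(self.values):
            raise ValueError("one value per window required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")
        if ((self.frame["end"] - self.frame["start"]) > self.width).any():
            raise ValueError("window longer than the tiling width")

    def __len__(self) -> int:
        return len(self.frame)

    def same_windows(self, other: "GenomicWindows") -> bool:
        return self.width == other.width and self.frame[
            ["chrom", "start", "end"]
        ].equals(other.frame[["chrom", "start", "end"]])


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph / interval TSV (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df["value"].isna().any():
        raise ValueError(f"{path}: missing values in the fourth column")
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chromosome-sizes TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def _tile(chrom_sizes: Mapping[str, int], width: int) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, width)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def bin_signal(
    intervals: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    width: int = DEFAULT_WIDTH,
    covered_only: bool = False,
) -> GenomicWindows:
    """Average interval values over fixed-width windows.

    Each window's value is the length-weighted mean of the interval values
    overlapping it; by default uncovered bases contribute 0 (coverage
    semantics), or set ``covered_only`` to average over covered bases only.
    Intervals must lie within their chromosome; overlapping input intervals
    have their contributions summed.
    """
    frame = _tile(chrom_sizes, width)
    values = np.zeros(len(frame))
    covered = np.zeros(len(frame))
    # window lookup: per-chromosome offset into the tiled frame
    offsets: dict[str, int] = {}
    counts: dict[str, int] = {}
    pos = 0
    for chrom, size in chrom_sizes.items():
        n = int(np.ceil(size / width))
        offsets[chrom] = pos
        counts[chrom] = n
        pos += n

    for chrom, grp in intervals.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        start = grp["start"].to_numpy(dtype=np.int64)
        end = grp["end"].to_numpy(dtype=np.int64)
        val = grp["value"].to_numpy(dtype=float)
        if (start < 0).any() or (end > size).any():
            raise ValueError(f"interval beyond the end of {chrom!r}")
        if (end <= start).any():
            raise ValueError("intervals must have positive length")
        first = start // width
        last = (end - 1) // width
        # split each interval across the windows it spans
        span = (last - first + 1).astype(np.int64)
        idx = np.repeat(first, span) + _ragged_arange(span)
        s = np.repeat(start, span)
        e = np.repeat(end, span)
        v = np.repeat(val, span)
        wstart = idx * width
        wend = np.minimum(wstart + width, size)
        overlap = np.minimum(e, wend) - np.maximum(s, wstart)
        at = offsets[chrom] + idx
        np.add.at(values, at, v * overlap)
        np.add.at(covered, at, overlap)

    widths = (frame["end"] - frame["start"]).to_numpy(dtype=float)
    if covered_only:
        with np.errstate(invalid="ignore"):
            out = np.where(covered > 0, values / np.maximum(covered, 1), 0.0)
    else:
        out = values / widths
    return GenomicWindows(frame=frame, values=out, width=width)


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """Concatenated arange(c) for each c in counts."""
    total = int(counts.sum())
    out = np.arange(total)
    out -= np.repeat(np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
    return out


@dataclass
class SampleManifest:
    """Per-sample file paths and (omics_group, tissue, replicate) labels.

    ``frame`` needs columns path, omics_group, tissue, replicate; the
    (omics_group, tissue, replicate) triples must be unique and the three
    label sets must form a complete grid for tensor assembly.
    """

    frame: pd.DataFrame
    _levels: dict = field(init=False, repr=False)

    REQUIRED = ("path", "omics_group", "tissue", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        trip = self.frame[["omics_group", "tissue", "replicate"]]
        if trip.duplicated().any():
            dup = trip[trip.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (omics_group, tissue, replicate) {dup}")
        self._levels = {
            col: list(dict.fromkeys(self.frame[col]))
            for col in ("omics_group", "tissue", "replicate")
        }

    @classmethod
    def from_csv(cls, path) -> "SampleManifest":
        return cls(pd.read_csv(path))

    def levels(self, col: str) -> list:
        """Levels of a design column, in manifest order of first appearance."""
        return self._levels[col]

    def __len__(self) -> int:
        return len(self.frame)


def assemble_tensor(
    manifest: SampleManifest,
    windows_by_sample: Mapping[str, GenomicWindows] | Sequence[GenomicWindows],
) -> OmicsTensor:
    """Stack per-sample window vectors into a 4-mode tensor.

    Modes: (window, omics_group, tissue, replicate), with level labels taken
    from the manifest (order of first appearance).  All samples must be
    binned on the identical window set; a missing (omics_group, tissue,
    replicate) slot is an explicit error naming the slot.
    """
    if not isinstance(windows_by_sample, Mapping):
        windows_by_sample = dict(zip(manifest.frame["path"], windows_by_sample))
    groups = manifest.levels("omics_group")
    tissues = manifest.levels("tissue")
    reps = manifest.levels("replicate")

    ref: GenomicWindows | None = None
    lookup: dict[tuple, GenomicWindows] = {}
    for _, row in manifest.frame.iterrows():
        key = (row["omics_group"], row["tissue"], row["replicate"])
        try:
            gw = windows_by_sample[row["path"]]
        except KeyError:
            raise ValueError(f"no binned windows for sample {row['path']!r}") from None
        if ref is None:
            ref = gw
        elif not gw.same_windows(ref):
            raise ValueError(
                f"window set of {row['path']!r} differs from the first sample"
            )
        lookup[key] = gw
    assert ref is not None

    values = np.empty((len(ref), len(groups), len(tissues), len(reps)))
    for a, g in enumerate(groups):
        for b, tis in enumerate(tissues):
            for c, rep in enumerate(reps):
                key = (g, tis, rep)
                if key not in lookup:
                    raise ValueError(
                        f"manifest has no sample for slot "
                        f"(omics_group={g!r}, tissue={tis!r}, replicate={rep!r})"
                    )
                values[:, a, b, c] = lookup[key].values
    window_ids = tuple(
        f"{r.chrom}:{r.start}-{r.end}" for r in ref.frame.itertuples()
    )
    return OmicsTensor(
        values,
        mode_names=("window", "omics_group", "tissue", "replicate"),
        level_labels=(window_ids, tuple(groups), tuple(tissues), tuple(reps)),
        feature_mode=0,
        metadata={"windows": ref.frame, "width": ref.width},
    )


def export_regions(
    windows: GenomicWindows,
    selected,
    path,
    p_adj=None,
) -> None:
    """Write selected windows as BED6.

    name = 0-based window index, score = -log10(adjusted p) capped at 1000
    (0 when no p-values are given), strand = ".".
    """
    selected = np.asarray(selected, dtype=bool)
    if selected.shape != (len(windows),):
        raise ValueError("mask length must equal the window count")
    with open(path, "w") as fh:
        fh.write("# BED6: selected genomic windows\n")
        for i in np.flatnonzero(selected):
            row = windows.frame.iloc[i]
            if p_adj is None:
                score = 0.0
            else:
                score = min(-np.log10(max(p_adj[i], 1e-300)), 1000.0)
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{i}\t{score:.4g}\t.\n"
            )


def read_regions(path, windows: GenomicWindows) -> np.ndarray:
    """Read a BED file written by :func:`export_regions` back into a mask."""
    mask = np.zeros(len(windows), dtype=bool)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if df.empty:
        return mask
    mask[df["name"].astype(int).to_numpy()] = True
    return mask


def count_genes_in_regions(
    regions: pd.DataFrame,
    annotation_path,
    biotype: str | None = "protein_coding",
) -> tuple[int, list[str]]:
    """Count genes whose span overlaps any selected region by >= 1 bp.

    ``regions`` needs columns chrom, start, end (0-based half-open).  The
    annotation (GTF or GFF3, 1-based inclusive, converted on read) is
    filtered to feature type ``gene`` and, when a ``biotype`` is given, to
    that gene biotype.  Each gene is counted once, however many regions it
    touches.  Returns the count and the sorted gene name list.
    """
    path = str(annotation_path)
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        ann = pr.read_gff3(path)
    else:
        ann = pr.read_gtf(path)
    df = ann.df
    df = df[df["Feature"] == "gene"]
    if biotype is not None:
        bt_col = next(
            (c for c in ("gene_biotype", "gene_type", "biotype") if c in df.columns),
            None,
        )
        if bt_col is None:
            logger.warning("annotation has no biotype attribute; counting all genes")
        else:
            df = df[df[bt_col] == biotype]
    name_col = next(
        (c for c in ("gene_name", "gene_id", "Name", "ID") if c in df.columns), None
    )
    if name_col is None or df.empty:
        return 0, []
    genes = pr.PyRanges(df[["Chromosome", "Start", "End", name_col]])
    sel = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": regions["chrom"].astype(str),
                "Start": regions["start"].astype(int),
                "End": regions["end"].astype(int),
            }
        )
    )
    hit = genes.join(sel)
    if hit.df.empty:
        return 0, []
    names = sorted(set(hit.df[name_col]))
    return len(names), names
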