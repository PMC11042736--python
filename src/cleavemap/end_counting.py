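"""Fragment reconstruction and strand-specific per-nucleotide 5'-end counting.

A sequencing *fragment* is the sequenced RNA molecule: a properly paired read
pair collapses to one fragment spanning the leftmost to the rightmost mapped
base (strand taken from read 1); an unpaired or orphaned mapped read stands
for a fragment equal to its own alignment span.  The fragment's 5'-most base
marks either a transcription start or the first nucleotide of the downstream
product of a cleavage event, which is what the whole pipeline is after.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

AXIS_NAMES = ("reference", "strand", "position")


@dataclass(frozen=True)
class FragmentRecord:
    """A reconstructed fragment (0-based half-open interval, stranded)."""

    reference_id: str
    strand: str
    start: int
    end: int

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


def fragments_from_alignments(
    alignment_path: str | os.PathLike,
    min_mapq: int = 0,
    primary_only: bool = True,
    pair_collapse: bool = True,
    stats: dict | None = None,
) -> list[FragmentRecord]:
    """Reconstruct fragments from a SAM/BAM file.

    Proper pairs yield one fragment (read 2 is skipped, the pair span is taken
    from read 1's mate information) when ``pair_collapse`` is true; otherwise
    every mapped read becomes its own fragment.  Secondary, supplementary and
    unmapped records, and records below ``min_mapq``, are skipped.  Malformed
    records are skipped with a warning; skip counters land in ``stats``.
    """
    counters = {
        "records": 0, "unmapped": 0, "secondary": 0, "low_mapq": 0,
        "malformed": 0, "mate_skipped": 0, "fragments": 0,
    }
    fragments: list[FragmentRecord] = []
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            counters["records"] += 1
            if aln.is_unmapped:
                counters["unmapped"] += 1
                continue
            if primary_only and (aln.is_secondary or aln.is_supplementary):
                counters["secondary"] += 1
                continue
            if aln.mapping_quality < min_mapq:
                counters["low_mapq"] += 1
                continue
            try:
                proper = (
                    pair_collapse
                    and aln.is_paired
                    and aln.is_proper_pair
                    and not aln.mate_is_unmapped
                    and aln.next_reference_id == aln.reference_id
                    and aln.template_length != 0
                )
                if proper:
                    if aln.is_read2:
                        counters["mate_skipped"] += 1
                        continue
                    start = min(aln.reference_start, aln.next_reference_start)
                    end = start + abs(aln.template_length)
                    strand = "-" if aln.is_reverse else "+"
                else:
                    start = aln.reference_start
                    end = aln.reference_end
                    if end is None:
                        raise ValueError("no aligned span")
                    strand = "-" if aln.is_reverse else "+"
                fragments.append(
                    FragmentRecord(aln.reference_name, strand, start, end)
                )
                counters["fragments"] += 1
            except (ValueError, TypeError) as exc:
                counters["malformed"] += 1
                logger.warning("skipping malformed record %s: %s", aln.query_name, exc)
    if stats is not None:
        stats.update(counters)
    return fragments


class EndCountTable:
    """Per-(reference, strand, position) 5'-end counts for a set of libraries.

    ``counts`` is a DataFrame indexed by the (reference, strand, position)
    axis (sparse: never-observed positions are not materialized) with one
    integer column per library.  ``library_sizes`` holds the total number of
    retained fragments per library, and ``meta`` the library metadata
    (``condition`` in {targeting, nontargeting}, ``replicate``,
    ``rpph_treated``).
    """

    def __init__(self, counts: pd.DataFrame, library_sizes: pd.Series,
                 meta: pd.DataFrame):
        counts = counts.copy()
        counts.index = counts.index.set_names(AXIS_NAMES)
        self.counts = counts
        self.library_sizes = library_sizes.astype(float).reindex(counts.columns)
        self.meta = meta.reindex(counts.columns)
        if (self.library_sizes < 0).any() or self.library_sizes.isna().any():
            raise ValueError("library sizes must be known and non-negative")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    # -- basic queries -------------------------------------------------
    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    def libraries_where(self, **flags) -> list[str]:
        """Library names whose metadata matches all given column=value pairs."""
        mask = pd.Series(True, index=self.meta.index)
        for col, val in flags.items():
            mask &= self.meta[col] == val
        return list(self.meta.index[mask])

    def subset_libraries(self, names: Sequence[str]) -> "EndCountTable":
        names = list(names)
        return EndCountTable(
            self.counts[names], self.library_sizes[names], self.meta.loc[names]
        )

    def subset_positions(self, index: pd.Index) -> "EndCountTable":
        return EndCountTable(
            self.counts.loc[index], self.library_sizes, self.meta
        )

    def cpm(self) -> pd.DataFrame:
        """Counts per million retained fragments (raw library sizes)."""
        return cpm_normalize(self)

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, prefix: str | os.PathLike) -> tuple[Path, Path]:
        """Write ``<prefix>.counts.tsv`` (1-based positions) + JSON sidecar."""
        prefix = Path(prefix)
        tsv = prefix.with_suffix(".counts.tsv")
        sidecar = prefix.with_suffix(".libraries.json")
        out = self.counts.reset_index()
        out["position"] = out["position"] + 1  # user-facing 1-based
        out.to_csv(tsv, sep="\t", index=False)
        payload = {
            "library_sizes": {k: float(v) for k, v in self.library_sizes.items()},
            "meta": {
                lib: {
                    "condition": str(row["condition"]),
                    "replicate": int(row["replicate"]),
                    "rpph_treated": bool(row["rpph_treated"]),
                }
                for lib, row in self.meta.iterrows()
            },
        }
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return tsv, sidecar

    @classmethod
    def from_tsv(cls, prefix: str | os.PathLike) -> "EndCountTable":
        prefix = Path(prefix)
        frame = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
        frame["position"] = frame["position"] - 1
        frame = frame.set_index(list(AXIS_NAMES))
        payload = json.loads(prefix.with_suffix(".libraries.json").read_text())
        sizes = pd.Series(payload["library_sizes"], dtype=float)
        meta = pd.DataFrame.from_dict(payload["meta"], orient="index")
        return cls(frame[list(sizes.index)], sizes, meta)


def make_library_meta(
    names: Sequence[str],
    conditions: Sequence[str],
    replicates: Sequence[int] | None = None,
    rpph_treated: Sequence[bool] | bool = True,
) -> pd.DataFrame:
    if replicates is None:
        replicates = list(range(1, len(names) + 1))
    if isinstance(rpph_treated, bool):
        rpph_treated = [rpph_treated] * len(names)
    return pd.DataFrame(
        {"condition": list(conditions), "replicate": list(replicates),
         "rpph_treated": list(rpph_treated)},
        index=list(names),
    )


def count_five_prime_ends(
    fragments: Mapping[str, Sequence[FragmentRecord]],
    meta: pd.DataFrame,
) -> EndCountTable:
    """Tally fragment 5' ends per strand-specific position for each library.

    ``fragments`` maps library name -> fragment list; the library size is the
    number of retained fragments, so column sums equal library sizes exactly.
    """
    columns = {}
    sizes = {}
    for lib, frags in fragments.items():
        if frags:
            idx = pd.MultiIndex.from_tuples(
                [(f.reference_id, f.strand, f.five_prime_pos) for f in frags],
                names=AXIS_NAMES,
            )
            columns[lib] = pd.Series(1, index=idx).groupby(level=[0, 1, 2]).sum()
        else:
            columns[lib] = pd.Series(
                dtype=int,
                index=pd.MultiIndex.from_arrays([[], [], []], names=AXIS_NAMES),
            )
        sizes[lib] = len(frags)
    counts = pd.DataFrame(columns).fillna(0).astype(int).sort_index()
    if (pd.Series(sizes) <= 0).all():
        raise ValueError("no fragments in any library")
    return EndCountTable(counts, pd.Series(sizes, dtype=float), meta)


def cpm_normalize(table_or_frame, library_sizes: pd.Series | None = None):
    """Scale counts to counts-per-million: ``counts * 1e6 / library_size``."""
    if isinstance(table_or_frame, EndCountTable):
        frame, sizes = table_or_frame.counts, table_or_frame.library_sizes
    else:
        frame, sizes = table_or_frame, library_sizes
        if sizes is None:
            raise ValueError("library_sizes required for a bare frame")
    if (np.asarray(sizes, dtype=float) <= 0).any():
        raise ValueError("library sizes must be positive for CPM")
    return frame * 1e6 / pd.Series(sizes, index=frame.columns)


@dataclass
class CoverageTrack:
    """Per-position fragment coverage over a region, with replicate summary."""

    reference_id: str
    strand: str
    start: int
    end: int
    coverage: pd.DataFrame        # positions x libraries, raw fragment counts
    cpm: pd.DataFrame             # CPM-normalized variant
    mean: pd.Series               # cross-replicate mean CPM
    sem: pd.Series                # standard error of the mean (0 when n = 1)


def coverage_profile(
    fragments: Mapping[str, Sequence[FragmentRecord]],
    library_sizes: Mapping[str, float],
    region: tuple[str, str, int, int],
) -> CoverageTrack:
    """Fragment coverage (mean +/- SEM of replicate CPM) over a stranded region."""
    ref, strand, start, end = region
    if start >= end:
        raise ValueError(f"empty region [{start}, {end})")
    positions = np.arange(start, end)
    cols = {}
    for lib, frags in fragments.items():
        depth = np.zeros(end - start, dtype=int)
        for f in frags:
            if f.reference_id != ref or f.strand != strand:
                continue
            lo, hi = max(f.start, start), min(f.end, end)
            if lo < hi:
                depth[lo - start : hi - start] += 1
        cols[lib] = depth
    coverage = pd.DataFrame(cols, index=pd.Index(positions, name="position"))
    sizes = pd.Series({k: float(library_sizes[k]) for k in coverage.columns})
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = coverage * 1e6 / sizes
    n = cpm.shape[1]
    mean = cpm.mean(axis=1)
    if n > 1:
        sem = cpm.std(axis=1, ddof=1) / np.sqrt(n)
    else:
        sem = pd.Series(0.0, index=cpm.index)
    return CoverageTrack(ref, strand, start, end, coverage, cpm, mean, sem)
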