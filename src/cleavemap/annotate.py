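"""Interpretive products built from called sites: feature assignment,
anticodon-loop profiles, sequence-logo matrices, volcano tables, and
multi-experiment transcript-level intersections.

Cleavage-position convention: a called 5'-end at position p means the
phosphodiester bond immediately 5' of p (in transcript orientation) was cut;
the fragment whose 5' end we observe is the downstream product.  The logo
window is therefore the 5 transcript-sense nucleotides 5' of the scissile
bond plus the 5 nucleotides 3' of it.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .end_counting import AXIS_NAMES
from .diff import ModelConfig
from .reference import (
    GenomeBundle,
    LOOP_POSITIONS,
    collapse_identical_trnas,
    reverse_complement,
)

logger = logging.getLogger(__name__)

LOGO_ALPHABET = ("A", "C", "G", "U")


def assign_sites_to_features(
    site_set: pd.DataFrame, genome: GenomeBundle
) -> pd.DataFrame:
    """Label each site with the overlapping same-strand feature and its class.

    Sites overlapping no same-strand feature are labeled ``antisense`` when a
    feature overlaps on the opposite strand, else ``intergenic``.  When
    several same-strand features overlap, the one whose start is nearest the
    site wins (logged).
    """
    by_ref: dict[str, list] = {}
    for f in genome.features:
        by_ref.setdefault(f.reference_id, []).append(f)
    names, classes = [], []
    for ref, strand, pos in site_set.index:
        feats = [f for f in by_ref.get(ref, []) if f.start <= pos < f.end]
        same = [f for f in feats if f.strand == strand]
        if same:
            if len(same) > 1:
                same.sort(key=lambda f: (abs(pos - f.start), f.name))
                logger.info(
                    "site %s:%s:%d overlaps %d features; chose %s",
                    ref, strand, pos, len(same), same[0].name,
                )
            names.append(same[0].name)
            classes.append(same[0].feature_class)
        elif feats:
            names.append("antisense:" + min(f.name for f in feats))
            classes.append("antisense")
        else:
            names.append("intergenic")
            classes.append("intergenic")
    out = site_set.copy()
    out["feature"] = names
    out["feature_class"] = classes
    out.attrs.update(site_set.attrs)
    return out


def anticodon_loop_profile(
    diff_result: pd.DataFrame,
    genome: GenomeBundle,
    collapse: bool = True,
) -> pd.DataFrame:
    """Per-tRNA-group profile of the anticodon loop (structural positions
    32-38, anticodon N1-N3 at 34-36).

    For each tRNA gene the seven loop offsets are mapped, strand-aware, to
    genomic positions and the log2 fold change and -log10(FDR) of those
    positions are collected from ``diff_result``.  Positions dropped by the
    CPM filter are absent (NaN), not zero-filled.  Genes are averaged within
    collapsed identical-sequence groups, and an ``__aggregate__`` row averages
    all groups with data at each loop position.
    """
    groups = collapse_identical_trnas(genome) if collapse else None
    rows: dict[str, dict] = {}
    counts: dict[str, dict] = {}
    for f in genome.trna_features():
        spec = genome.trna_index.get(f.name)
        if spec is None:
            logger.warning("tRNA %s lacks an anticodon spec; skipped", f.name)
            continue
        label = groups[f.name] if groups else f.name
        row = rows.setdefault(label, {})
        cnt = counts.setdefault(label, {})
        for loop_pos in LOOP_POSITIONS:
            gpos = f.transcript_to_genomic(spec.loop_offset(loop_pos))
            key = (f.reference_id, f.strand, gpos)
            if key not in diff_result.index:
                continue
            rec = diff_result.loc[key]
            fdr = rec["fdr"]
            nlfdr = -np.log10(max(float(fdr), 1e-300)) if pd.notna(fdr) else np.nan
            for stat, val in (("log2fc", float(rec["log2fc"])), ("neglog10_fdr", nlfdr)):
                col = (stat, loop_pos)
                if pd.isna(val):
                    continue
                row[col] = row.get(col, 0.0) + val
                cnt[col] = cnt.get(col, 0) + 1
    for label, row in rows.items():
        for col in row:
            row[col] /= counts[label][col]
    profile = pd.DataFrame.from_dict(rows, orient="index")
    if profile.empty:
        return pd.DataFrame(
            columns=pd.MultiIndex.from_product([["log2fc", "neglog10_fdr"],
                                                LOOP_POSITIONS])
        )
    profile.columns = pd.MultiIndex.from_tuples(profile.columns,
                                                names=["stat", "loop_position"])
    profile = profile.sort_index().sort_index(axis=1)
    profile.loc["__aggregate__"] = profile.mean(axis=0, skipna=True)
    return profile


def build_logo_matrix(
    site_set: pd.DataFrame,
    genome: GenomeBundle,
    flank: int = 5,
) -> pd.DataFrame:
    """Nucleotide-frequency matrix of the sequence context around the cleavage
    phosphate (``flank`` nt on each side, transcript orientation; 10 columns
    at the default).

    Columns are offsets -flank..-1 (5' of the bond) and +1..+flank (3' of
    it, starting at the called 5'-end base); rows are A/C/G/U frequencies
    summing to 1.  Sites too close to a sequence edge are dropped and counted
    in ``attrs['n_dropped']``.
    """
    windows = []
    dropped = 0
    for ref, strand, pos in site_set.index:
        seq = genome.sequences[ref]
        if strand == "+":
            lo, hi = pos - flank, pos + flank
            if lo < 0 or hi > len(seq):
                dropped += 1
                continue
            windows.append(seq[lo:hi])
        else:
            lo, hi = pos - flank + 1, pos + flank + 1
            if lo < 0 or hi > len(seq):
                dropped += 1
                continue
            windows.append(reverse_complement(seq[lo:hi]))
    if not windows:
        raise ValueError("all sites fell too close to a sequence edge")
    offsets = list(range(-flank, 0)) + list(range(1, flank + 1))
    mat = pd.DataFrame(0.0, index=list(LOGO_ALPHABET), columns=offsets)
    for w in windows:
        for off, base in zip(offsets, w):
            base = "U" if base == "T" else base
            if base in mat.index:
                mat.loc[base, off] += 1.0
    col_tot = mat.sum(axis=0)
    mat = mat / col_tot.replace(0, np.nan)
    mat = mat.fillna(0.0)
    mat.attrs["n_sites"] = len(windows)
    mat.attrs["n_dropped"] = dropped
    return mat


def plot_logo(logo: pd.DataFrame, path, figsize=(6, 2)):  # pragma: no cover
    """Optional PNG rendering of a logo matrix as stacked letters."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "U": "#e31a1c"}
    fig, ax = plt.subplots(figsize=figsize)
    for i, col in enumerate(logo.columns):
        bottom = 0.0
        for base in logo.index[np.argsort(logo[col].to_numpy())]:
            h = logo.loc[base, col]
            if h <= 0:
                continue
            ax.text(i, bottom + h / 2, base, ha="center", va="center",
                    fontsize=8 + 14 * h, color=colors.get(base, "k"))
            bottom += h
    ax.axvline(len([c for c in logo.columns if c < 0]) - 0.5, ls="--", c="k")
    ax.set_xticks(range(len(logo.columns)), [str(c) for c in logo.columns])
    ax.set_ylim(0, 1)
    ax.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def volcano_table(
    diff_result: pd.DataFrame,
    annotated: pd.DataFrame | None,
    config: ModelConfig,
) -> pd.DataFrame:
    """Per-position export for volcano plotting: log2fc, -log10(FDR), feature
    assignment, and the two threshold flags (within the top-N FDR cutoff;
    log2fc strictly above the fold-change line)."""
    if diff_result.empty:
        return pd.DataFrame(
            columns=["log2fc", "neglog10_fdr", "feature", "feature_class",
                     "above_fdr_cutoff", "above_lfc_threshold"]
        )
    out = diff_result[["log2fc"]].copy()
    fdr = diff_result["fdr"]
    out["neglog10_fdr"] = -np.log10(fdr.clip(lower=1e-300))
    if annotated is not None and "feature" in annotated.columns:
        out["feature"] = annotated["feature"].reindex(out.index)
        out["feature_class"] = annotated["feature_class"].reindex(out.index)
    else:
        out["feature"] = "unassigned"
        out["feature_class"] = "unassigned"
    finite = fdr.dropna().sort_values()
    cutoff = finite.iloc[min(config.top_n, len(finite)) - 1] if len(finite) else np.nan
    out["above_fdr_cutoff"] = fdr <= cutoff
    out["above_lfc_threshold"] = out["log2fc"] > config.lfc_threshold
    return out


def _site_transcripts(
    sites: pd.DataFrame, genome: GenomeBundle, trna_groups: Mapping[str, str]
) -> set[str]:
    if "feature" not in sites.columns:
        sites = assign_sites_to_features(sites, genome)
    out = set()
    for (ref, strand, pos), row in sites.iterrows():
        name, fclass = row["feature"], row["feature_class"]
        if fclass == "tRNA":
            out.add(trna_groups.get(name, name))
        elif fclass in ("intergenic", "antisense"):
            out.add(f"{fclass}:{ref}:{strand}:{pos + 1}")
        else:
            out.add(name)
    return out


def intersect_experiments(
    site_sets: Sequence[tuple[str, pd.DataFrame]] | Mapping[str, pd.DataFrame],
    genome: GenomeBundle,
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Transcript-level intersection of site sets from multiple experiments.

    Each site maps to its transcript — tRNA sites to the collapsed
    identical-sequence tRNA group, other sites to the feature name — because
    the same RNA may be cleaved at different positions in different
    experiments.  Returns the per-transcript boolean membership matrix and
    Venn-region counts keyed by frozenset of set names (regions sum to the
    union size).
    """
    if isinstance(site_sets, Mapping):
        pairs = list(site_sets.items())
    else:
        pairs = list(site_sets)
    names = [n for n, _ in pairs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate experiment names")
    if len(pairs) < 2:
        raise ValueError("need at least two site sets to intersect")
    trna_groups = collapse_identical_trnas(genome)
    transcripts = {n: _site_transcripts(s, genome, trna_groups) for n, s in pairs}
    universe = sorted(set().union(*transcripts.values()))
    membership = pd.DataFrame(
        {n: [t in transcripts[n] for t in universe] for n in names},
        index=pd.Index(universe, name="transcript"),
    )
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            key = frozenset(combo)
            in_these = membership[list(combo)].all(axis=1)
            out_rest = ~membership[[n for n in names if n not in combo]].any(axis=1) \
                if len(combo) < len(names) else pd.Series(True, index=membership.index)
            regions[key] = int((in_these & out_rest).sum())
    return membership, regions
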