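"""Self-contained synthetic fixtures: genome + annotation, per-position 5'-end
count tables with implanted cleavage/TSS signal, paired-end SAM files, and the
ground truth needed to verify every pipeline stage.

The generative model mirrors what the statistical test assumes: per-position
expected 5'-end intensities (uniform background fragmentation within each
expressed feature, concentrated mass at transcription starts, and
condition-specific multipliers at implanted cleavage positions), with
replicate counts drawn NB(mean, dispersion).  RppH-untreated libraries see
the TSS mass reduced by the RppH enrichment factor — primary 5'-triphosphate
ends only become ligatable after conversion — while cleavage-derived
5'-monophosphate ends are treatment-independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.Seq import Seq

from .end_counting import AXIS_NAMES, EndCountTable
from .reference import (
    AnticodonSpec,
    Feature,
    GenomeBundle,
    N1_LOOP_POSITION,
    reverse_complement,
    write_annotation,
    write_genome,
)

_SUFFIXES = "TUVWXYZABCDEFGHIJKLMNOPQRS"
_MARGIN = 200  # clearance kept around features and noise positions


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate the structure of the real libraries: three targeting and
    three nontargeting biological replicates of 2x35 nt paired-end reads,
    NB replicate noise, tRNA genes cycling through anticodons that include
    the U-rich set (UUU/UUC/UUG/UGU), highly expressed tRNAs over a CDS
    background, TSS peaks at feature starts enriched 8-fold by RppH
    treatment, and cleavage implants placed mostly at the first anticodon
    nucleotide.
    """

    seed: int = 0
    n_refs: int = 1
    n_cds: int = 12
    cds_length_range: tuple[int, int] = (200, 600)
    n_trna: int = 24
    anticodons: tuple[str, ...] = (
        "TTT", "TTC", "TTG", "TGT",          # U-rich (RNA: UUU/UUC/UUG/UGU)
        "GCA", "CAT", "GAA", "CGG",
    )
    trna_length: int = 76
    anticodon_n1_offset: int = 34
    urich_copy_weight: float = 5.0   # gene-copy bias toward U-rich anticodons
    n_replicates: int = 3
    depth: float = 180_000.0          # expected fragments per library
    dispersion: float = 0.15          # NB dispersion shared by all positions
    per_position_dispersion: bool = False  # stress mode: gamma-distributed phi
    trna_expression: float = 75.0     # per-position weight of tRNA positions
    cds_expression: float = 8.0
    rrna_expression: float = 20.0
    expression_sigma: float = 0.08    # lognormal feature-to-feature spread
    tss_strength: float = 12.0        # TSS mass relative to local background
    tss_rpph_enrichment: float = 8.0
    noise_positions: int = 800
    noise_fraction: float = 0.003
    read_length: int = 35
    fragment_length_range: tuple[int, int] = (60, 180)
    with_rpph_untreated: bool = False
    n1_fraction: float = 0.9          # fraction of auto-implants at N1
    implanted_cleavage: tuple[tuple[str, int, float], ...] = ()
    implanted_tss: tuple[tuple[str, str, int, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for _, _, eff in self.implanted_cleavage:
            if not np.isfinite(eff):
                raise ValueError("implant effects must be finite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cds_length_range"] = list(self.cds_length_range)
        d["fragment_length_range"] = list(self.fragment_length_range)
        d["anticodons"] = list(self.anticodons)
        d["implanted_cleavage"] = [list(t) for t in self.implanted_cleavage]
        d["implanted_tss"] = [list(t) for t in self.implanted_tss]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("cds_length_range", "fragment_length_range", "anticodons"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("implanted_cleavage", "implanted_tss"):
            if key in d:
                d[key] = tuple(tuple(t) for t in d[key])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of implanted signal, for recovery tests."""

    cleavage: list[dict] = field(default_factory=list)
    tss: list[dict] = field(default_factory=list)

    def cleavage_positions(self) -> set[tuple[str, str, int]]:
        return {(d["reference"], d["strand"], d["position"]) for d in self.cleavage}

    def tss_positions(self) -> set[tuple[str, str, int]]:
        return {(d["reference"], d["strand"], d["position"]) for d in self.tss}

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"cleavage": self.cleavage, "tss": self.tss},
                       indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(cleavage=d["cleavage"], tss=d["tss"])


def _anticodon_family(anticodon: str, used: dict[str, str]) -> str:
    """Family name from the amino acid the anticodon decodes (lys, glu, ...)."""
    codon = reverse_complement(anticodon)
    aa = str(Seq(codon).translate())
    name = protein_letters_1to3.get(aa, "unk").lower()
    if name in used and used[name] != anticodon:
        name = name + anticodon.lower()
    used[name] = anticodon
    return name


def generate_reference(config: SimConfig, out_dir=None) -> GenomeBundle:
    """Build a random genome with embedded CDS and tRNA genes.

    tRNA genes of the same anticodon family share a byte-identical gene body
    (so identical-sequence collapsing has something to do), each carrying its
    declared anticodon at the annotated N1 offset.  Writes ``genome.fasta``
    and ``annotation.bed`` into ``out_dir`` when given.
    """
    rng = np.random.default_rng([config.seed, 101])
    if config.anticodon_n1_offset + 5 > config.trna_length:
        raise ValueError("anticodon does not fit in the tRNA body")

    # gene bodies per anticodon family (identical within a family)
    used: dict[str, str] = {}
    families = []
    for ac in config.anticodons:
        body = rng.choice(list("ACGT"), size=config.trna_length)
        body[config.anticodon_n1_offset : config.anticodon_n1_offset + 3] = list(ac)
        families.append((_anticodon_family(ac, used), ac, "".join(body)))

    # multi-copy allocation: U-rich-anticodon families get more gene copies,
    # mirroring the multiple identical lys/gln/glu/thr tRNA genes of E. coli
    weights = np.array(
        [config.urich_copy_weight if ac.count("T") >= 2 else 1.0
         for _, ac, _ in families]
    )
    copies = np.floor(weights * config.n_trna / weights.sum()).astype(int)
    copies = np.maximum(copies, 1)
    while copies.sum() < config.n_trna:
        copies[int(np.argmax(weights / np.maximum(copies, 1)))] += 1
    while copies.sum() > config.n_trna:
        copies[int(np.argmax(copies))] -= 1

    genes: list[tuple[str, str, str, str]] = []  # (name, class, seq, anticodon)
    counters = {name: 0 for name, _, _ in families}
    for (name, ac, body), k in zip(families, copies):
        for _ in range(int(k)):
            suffix = _SUFFIXES[counters[name] % len(_SUFFIXES)]
            counters[name] += 1
            genes.append((name + suffix, "tRNA", body, ac))
    for i in range(config.n_cds):
        length = int(rng.integers(*config.cds_length_range))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        genes.append((f"orf{i + 1:03d}", "CDS", seq, ""))

    # shuffle deterministically so strands/positions interleave classes
    order = rng.permutation(len(genes))
    genes = [genes[int(i)] for i in order]

    per_ref: list[list] = [[] for _ in range(config.n_refs)]
    for i, gene in enumerate(genes):
        per_ref[i % config.n_refs].append(gene)

    sequences: dict[str, str] = {}
    features: list[Feature] = []
    trna_index: dict[str, AnticodonSpec] = {}
    for r, ref_genes in enumerate(per_ref):
        ref_id = f"chrom{r + 1}"
        cursor = _MARGIN + int(rng.integers(0, 50))
        placed = []
        for name, fclass, seq, ac in ref_genes:
            start, end = cursor, cursor + len(seq)
            strand = "+" if rng.random() < 0.5 else "-"
            placed.append((name, fclass, seq, ac, start, end, strand))
            cursor = end + _MARGIN + int(rng.integers(0, 100))
        ref_len = cursor + _MARGIN
        arr = rng.choice(list("ACGT"), size=ref_len)
        for name, fclass, seq, ac, start, end, strand in placed:
            ins = seq if strand == "+" else reverse_complement(seq)
            arr[start:end] = list(ins)
            features.append(Feature(name, ref_id, start, end, strand, fclass))
            if fclass == "tRNA":
                trna_index[name] = AnticodonSpec(
                    anticodon_seq=ac, n1_offset=config.anticodon_n1_offset
                )
        sequences[ref_id] = "".join(arr)

    bundle = GenomeBundle(sequences=sequences, features=features,
                          trna_index=trna_index)
    bundle.validate()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genome(bundle, out_dir / "genome.fasta")
        write_annotation(bundle, out_dir / "annotation.bed")
    return bundle


def default_cleavage_implants(
    bundle: GenomeBundle,
    config: SimConfig,
    n: int | None = 20,
    effect: float = 6.0,
    min_uridines: int = 2,
) -> tuple[tuple[str, int, float], ...]:
    """Implants at anticodon loops of U-rich-anticodon tRNAs.

    A fraction ``config.n1_fraction`` of the implants goes to the first
    anticodon nucleotide (loop position 34); the rest cycle through the other
    anticodon positions.  Genes are taken in sorted name order for
    determinism.
    """
    eligible = sorted(
        f.name for f in bundle.trna_features()
        if bundle.trna_index[f.name].anticodon_seq.count("T") >= min_uridines
    )
    if n is None:
        n = min(20, len(eligible))
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} U-rich tRNA genes available for {n} implants"
        )
    n_at_n1 = int(np.ceil(config.n1_fraction * n))
    implants = []
    other_positions = (35, 36)
    for i, gene in enumerate(eligible[:n]):
        loop_pos = (N1_LOOP_POSITION if i < n_at_n1
                    else other_positions[(i - n_at_n1) % len(other_positions)])
        implants.append((gene, loop_pos, effect))
    return tuple(implants)


def _class_expression(config: SimConfig, fclass: str) -> float:
    return {"tRNA": config.trna_expression, "CDS": config.cds_expression,
            "rRNA": config.rrna_expression}.get(fclass, config.cds_expression)


def simulate_counts(
    config: SimConfig, bundle: GenomeBundle
) -> tuple[EndCountTable, SimTruth]:
    """Draw per-position 5'-end count tables for all libraries.

    Background 5' ends are spread uniformly across each feature's strand
    (feature abundance x uniform fragmentation); TSS positions at feature 5'
    starts carry concentrated extra mass present in both conditions but
    reduced ``tss_rpph_enrichment``-fold in untreated libraries; implanted
    cleavage positions have their mean multiplied by 2**effect in targeting
    libraries only.  Replicates are NB(mean, dispersion); library sizes are
    the realized column totals.
    """
    rng = np.random.default_rng([config.seed, 202])

    refs, strands, positions, weights = [], [], [], []
    tss_records = []
    for f in bundle.features:
        expr = _class_expression(config, f.feature_class) * float(
            rng.lognormal(0.0, config.expression_sigma)
        )
        refs.extend([f.reference_id] * f.length)
        strands.extend([f.strand] * f.length)
        if f.strand == "+":
            positions.extend(range(f.start, f.end))
        else:
            positions.extend(range(f.start, f.end))
        weights.extend([expr] * f.length)
        tss_records.append(
            (f.reference_id, f.strand, f.five_prime_pos,
             config.tss_strength, config.tss_rpph_enrichment, f.name)
        )
    feature_mass = float(np.sum(weights))

    # sparse random background noise outside/inside features
    for _ in range(config.noise_positions):
        ref_id = list(bundle.sequences)[int(rng.integers(0, len(bundle.sequences)))]
        L = len(bundle.sequences[ref_id])
        refs.append(ref_id)
        strands.append("+" if rng.random() < 0.5 else "-")
        positions.append(int(rng.integers(_MARGIN, L - _MARGIN)))
        weights.append(config.noise_fraction * feature_mass
                       / max(config.noise_positions, 1))

    base = (
        pd.Series(
            weights,
            index=pd.MultiIndex.from_arrays([refs, strands, positions],
                                            names=AXIS_NAMES),
        )
        .groupby(level=[0, 1, 2]).sum().sort_index()
    )

    # TSS mass (auto at feature starts + explicit implants)
    for ref, strand, pos, strength, enr in config.implanted_tss:
        if (ref, strand, pos) not in base.index:
            raise ValueError(
                f"implanted TSS {ref}:{strand}:{pos} lies outside expressed features"
            )
        tss_records.append((ref, strand, pos, strength, enr, "implanted"))
    tss_mass = pd.Series(0.0, index=base.index)
    tss_enr = pd.Series(config.tss_rpph_enrichment, index=base.index)
    truth = SimTruth()
    for ref, strand, pos, strength, enr, source in tss_records:
        key = (ref, strand, pos)
        tss_mass.loc[key] = strength * base.loc[key]
        tss_enr.loc[key] = enr
        truth.tss.append(
            {"reference": ref, "strand": strand, "position": int(pos),
             "strength": float(strength), "rpph_enrichment": float(enr),
             "source": source}
        )

    # cleavage multipliers (targeting libraries only)
    cleav_mult = pd.Series(1.0, index=base.index)
    for gene, loop_pos, effect in config.implanted_cleavage:
        f = bundle.get_feature(gene)
        spec = bundle.trna_index[gene]
        gpos = f.transcript_to_genomic(spec.loop_offset(loop_pos))
        key = (f.reference_id, f.strand, gpos)
        cleav_mult.loc[key] = 2.0 ** effect
        truth.cleavage.append(
            {"reference": f.reference_id, "strand": f.strand,
             "position": int(gpos), "gene": gene, "loop_position": int(loop_pos),
             "effect": float(effect),
             "baseline_mean": float("nan")}  # filled below
        )

    # reference intensity: nontargeting, RppH-treated library
    intensity_ref = base + tss_mass
    Z = intensity_ref.sum()
    unit = config.depth / Z

    phi = config.dispersion
    if config.per_position_dispersion and phi > 0:
        phi_vec = rng.gamma(shape=2.0, scale=phi / 2.0, size=len(base))
    else:
        phi_vec = None

    treatments = [True, False] if config.with_rpph_untreated else [True]
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for condition in ("targeting", "nontargeting"):
        cmult = cleav_mult if condition == "targeting" else 1.0
        for treated in treatments:
            tmass = tss_mass if treated else tss_mass / tss_enr
            mean = ((base + tmass) * cmult * unit).to_numpy()
            for rep in range(1, config.n_replicates + 1):
                trt = "treated" if treated else "untreated"
                lib = f"{condition}_{trt}_rep{rep}"
                if phi == 0:
                    draw = rng.poisson(mean)
                else:
                    pvec = phi_vec if phi_vec is not None else np.full_like(mean, phi)
                    r = 1.0 / pvec
                    p = r / (r + np.maximum(mean, 1e-300))
                    draw = rng.negative_binomial(r, p)
                    draw[mean == 0] = 0
                columns[lib] = draw
                meta_rows.append((lib, condition, rep, treated))

    counts = pd.DataFrame(columns, index=base.index)
    counts = counts[counts.sum(axis=1) > 0]
    meta = pd.DataFrame(
        [(c, r, t) for _, c, r, t in meta_rows],
        index=[m[0] for m in meta_rows],
        columns=["condition", "replicate", "rpph_treated"],
    )
    sizes = counts.sum(axis=0).astype(float)
    table = EndCountTable(counts, sizes, meta)

    for rec in truth.cleavage:
        key = (rec["reference"], rec["strand"], rec["position"])
        rec["baseline_mean"] = float((base.loc[key] + tss_mass.loc[key]) * unit)
    return table, truth


def simulate_alignments(
    config: SimConfig,
    bundle: GenomeBundle,
    table: EndCountTable,
    out_dir,
) -> dict[str, Path]:
    """Emit one paired-end SAM file per library realizing ``table`` exactly.

    Every counted 5' end becomes one properly paired fragment (two
    ``read_length``-nt reads) whose 5'-most base sits at the counted
    position, so re-counting the SAM reproduces the table.
    """
    rng = np.random.default_rng([config.seed, 303])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    R = config.read_length
    lo, hi = config.fragment_length_range

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for ref_id, seq in bundle.sequences.items():
        header_lines.append(f"@SQ\tSN:{ref_id}\tLN:{len(seq)}")
    header = "\n".join(header_lines) + "\n"

    index = table.counts.index
    paths: dict[str, Path] = {}
    for lib in table.libraries:
        col = table.counts[lib].to_numpy()
        lines: list[str] = []
        serial = 0
        for (ref, strand, pos), c in zip(index, col):
            if c == 0:
                continue
            seq = bundle.sequences[ref]
            ref_len = len(seq)
            lengths = rng.integers(lo, hi + 1, size=int(c))
            for L in lengths:
                L = int(L)
                if strand == "+":
                    L = min(L, ref_len - pos)
                    s, e = pos, pos + L
                else:
                    L = min(L, pos + 1)
                    s, e = pos - L + 1, pos + 1
                if L < R:  # cannot happen with default margins; safety clamp
                    continue
                serial += 1
                qname = f"{lib}:{serial}"
                tlen = e - s
                seq1 = seq[s : s + R]
                seq2 = seq[e - R : e]
                qual = "I" * R
                if strand == "+":
                    lines.append(
                        f"{qname}\t99\t{ref}\t{s + 1}\t60\t{R}M\t=\t{e - R + 1}"
                        f"\t{tlen}\t{seq1}\t{qual}"
                    )
                    lines.append(
                        f"{qname}\t147\t{ref}\t{e - R + 1}\t60\t{R}M\t=\t{s + 1}"
                        f"\t{-tlen}\t{seq2}\t{qual}"
                    )
                else:
                    lines.append(
                        f"{qname}\t83\t{ref}\t{e - R + 1}\t60\t{R}M\t=\t{s + 1}"
                        f"\t{-tlen}\t{seq2}\t{qual}"
                    )
                    lines.append(
                        f"{qname}\t163\t{ref}\t{s + 1}\t60\t{R}M\t=\t{e - R + 1}"
                        f"\t{tlen}\t{seq1}\t{qual}"
                    )
        path = out_dir / f"{lib}.sam"
        path.write_text(header + "\n".join(lines) + ("\n" if lines else ""))
        paths[lib] = path
    return paths
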