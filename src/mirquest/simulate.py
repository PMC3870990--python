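"""Synthetic small-RNA study generator with planted ground truth.

Emulates the structure of a small-RNA sequencing experiment on a toy
genome: known miRNA hairpins (some present as two genomic copies of one
family, so family collapsing is exercised), novel two-arm hairpins whose
mature/star arms are absent from the mature reference, contaminant loci
(rRNA/tRNA/repeat/adapter), and decoy loci whose insert is a shuffled
hairpin (expressed, but with no clean stem — discovery should not promote
them).  Per-locus expression is Poisson-distributed with per-library fold
multipliers so differential-expression calling is exercised under sampling
noise; a fixed-count mode gives exact counts for conservation tests.

All genomic files are DNA-alphabet; structures switch to the RNA view only
inside :mod:`mirquest.structure`.  Reads for both libraries share one FASTQ
with the library encoded as an ``L<k>|`` prefix of the read id.  With the
seed fixed the whole fixture bundle is byte-identical between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    gff3_attributes,
    revcomp,
    write_fasta,
    write_fastq,
    write_gff3,
    write_manifest,
)

__all__ = ["SimConfig", "plant_hairpin", "generate_genome", "simulate_reads", "make_fixture", "Fixture"]

_BASES = np.array(list("ACGT"))

#: Probability of trimming 0, 1, 2, ... nt from a read end (renormalised to
#: the configured maximum jitter).  Most reads keep canonical ends, as in
#: real small-RNA libraries where templated ends dominate over isomiRs.
_JITTER_WEIGHTS = (0.8, 0.15, 0.05)


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a two-library comparison (normal-like ``L1`` vs
    tumour-like ``L2``) with a mean of 100 read copies per locus, a tenfold
    dominant miRNA anchoring the library maximum, planted 4-fold
    differential loci in both directions, one library-unique miRNA, and a
    0.5% per-base substitution error rate.
    """

    genome_length: int = 60_000
    n_known_mirnas: int = 12
    n_novel_hairpins: int = 3
    n_contaminant_loci: int = 4
    n_decoy_loci: int = 2
    n_libraries: int = 2
    mature_length_range: tuple[int, int] = (19, 22)
    loop_length: tuple[int, int] = (8, 15)
    arm_mismatch_rate: float = 0.0
    wobble_rate: float = 0.1
    expression_mean_per_locus: float = 100.0
    read_end_jitter: int = 2
    error_rate: float = 0.005
    star_fraction: float = 0.5
    fixed_counts: bool = False
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("arm_mismatch_rate", "error_rate", "star_fraction", "wobble_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_end_jitter < 0 or self.read_end_jitter >= len(_JITTER_WEIGHTS) + 1:
            raise ValueError("read_end_jitter must be 0, 1 or 2")
        if self.n_libraries < 1:
            raise ValueError("need at least one library")
        needed = 1000 + 600 * self.n_loci
        if self.genome_length < needed:
            raise ValueError(
                f"genome_length {self.genome_length} too small for "
                f"{self.n_loci} planted loci (need >= {needed})"
            )

    @property
    def n_loci(self) -> int:
        return (
            self.n_known_mirnas
            + self.n_novel_hairpins
            + self.n_contaminant_loci
            + self.n_decoy_loci
        )

    @property
    def libraries(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_libraries)]


TRUTH_COLUMNS = [
    "locus_id", "klass", "chrom", "start", "end", "strand",
    "mature_start", "mature_end", "mature_seq", "star_seq", "star_start", "star_end",
    "mature_name", "family_key", "contaminant_class", "de_group",
]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def generate_genome(config: SimConfig) -> str:
    """Uniform-random DNA background of ``genome_length`` nt (seeded)."""
    rng = np.random.default_rng(config.seed)
    return _rand_seq(rng, config.genome_length)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def _apply_wobbles(mature: str, arm3: str, rate: float, rng: np.random.Generator) -> str:
    """Turn Watson–Crick pairs of the 3' arm into G·U wobbles at ``rate``.

    Where the mature arm carries G the complementary C becomes T (G·U in
    the fold) and where it carries T the complementary A becomes G (U·G).
    At least one wobble is forced whenever any position allows it: real
    precursor stems are wobble-rich, and without one the construct is a
    perfect inverted repeat whose reads map to both genome strands.
    """
    arm = list(arm3)
    n = len(mature)
    eligible = [i for i, b in enumerate(mature) if b in "GT"]
    chosen = [i for i in eligible if rng.random() < rate]
    if not chosen and eligible:
        chosen = [eligible[int(rng.integers(len(eligible)))]]
    for i in chosen:
        # mature position i pairs with arm3 position n-1-i
        arm[n - 1 - i] = "T" if mature[i] == "G" else "G"
    return "".join(arm)


def plant_hairpin(
    genome: str,
    mature_seq: str,
    loop_len: int,
    position: int,
    strand: str,
    arm_mismatch_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    locus_id: str = "hairpin",
    klass: str = "novel_hairpin",
    wobble_rate: float = 0.1,
) -> tuple[str, dict]:
    """Overwrite a genome segment with a hairpin construct and return its truth row.

    The transcript-sense construct is ``mature + loop + revcomp(mature)``;
    the 3' arm carries G·U wobble pairs at ``wobble_rate`` (still paired in
    the fold, but breaking perfect inverted-repeat symmetry at the DNA
    level, as in real precursors) and unpaired mismatches at
    ``arm_mismatch_rate``.  On the minus strand the genome stores the
    reverse complement, so the strand-adjusted genome substring always
    reads as the construct.  The truth row records the genomic interval of
    the mature arm (and of the star arm, whose genome-derived sequence is
    the star read).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if len(mature_seq) < 15:
        raise ValueError("mature sequence must be at least 15 nt")
    arm3 = _apply_wobbles(mature_seq, revcomp(mature_seq), wobble_rate, rng)
    arm3 = _mutate(arm3, arm_mismatch_rate, rng)
    construct = mature_seq + _rand_seq(rng, loop_len) + arm3
    total = len(construct)
    if position < 0 or position + total > len(genome):
        raise IndexError(
            f"hairpin at {position}..{position + total} outside genome of length {len(genome)}"
        )
    genomic = construct if strand == "+" else revcomp(construct)
    new_genome = genome[:position] + genomic + genome[position + total:]
    mlen = len(mature_seq)
    if strand == "+":
        mstart, mend = position, position + mlen
        sstart, send = position + total - mlen, position + total
    else:
        mstart, mend = position + total - mlen, position + total
        sstart, send = position, position + mlen
    # star read: transcript-sense sequence of the 3' arm (genome-derived)
    star_seq = arm3
    row = {
        "locus_id": locus_id,
        "klass": klass,
        "chrom": "",
        "start": position,
        "end": position + total,
        "strand": strand,
        "mature_start": mstart,
        "mature_end": mend,
        "mature_seq": mature_seq,
        "star_seq": star_seq,
        "star_start": sstart,
        "star_end": send,
        "mature_name": "",
        "family_key": "",
        "contaminant_class": "",
        "de_group": "",
    }
    return new_genome, row


_CONTAMINANT_CLASSES = ["rRNA", "tRNA", "repeat", "adapter"]
_CONTAMINANT_LENGTHS = {"rRNA": 150, "tRNA": 75, "repeat": 180, "adapter": 30}


@dataclass
class Fixture:
    """In-memory view of a generated study bundle."""

    config: SimConfig
    genome: str
    truth: pd.DataFrame
    mature_reference: list[tuple[str, str, str]]      # (mature_name, description, seq)
    family_map: pd.DataFrame                          # mature_name, precursor_id, family_key
    contaminants: list[tuple[str, str, str]]
    ncrna_db: list[tuple[str, str, str]]
    annotation: pd.DataFrame
    reads: list[tuple[str, str, str]] = field(default_factory=list)   # (read_id, library, seq)
    read_truth: dict[str, str] = field(default_factory=dict)          # read_id -> locus_id
    paths: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def build_truth(config: SimConfig) -> Fixture:
    """Plant all loci on a fresh genome and assemble references and truth.

    Locus layout (deterministic per seed): known miRNA hairpins first (the
    first two genomic copies share one family and an identical mature
    sequence; one known locus is ten-fold dominant; two are 4-fold up in
    L1, two 4-fold up in L2; one is expressed only in L1), then novel
    hairpins (the last one sits inside an annotated intron), then decoys
    (the last one sits inside an annotated exon), then contaminant loci.
    """
    rng = np.random.default_rng(config.seed)
    genome = _rand_seq(rng, config.genome_length)

    n = config.n_loci
    usable = config.genome_length - 1000
    slot = usable // n
    positions = [500 + i * slot for i in range(n)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(n)]

    rows: list[dict] = []
    mature_reference: list[tuple[str, str, str]] = []
    family_rows: list[dict] = []
    contaminants: list[tuple[str, str, str]] = []
    ncrna_db: list[tuple[str, str, str]] = []
    ann_rows: list[dict] = []

    mlo, mhi = config.mature_length_range
    llo, lhi = config.loop_length
    slot_iter = iter(range(n))

    def plant_screened(
        genome: str,
        position: int,
        strand: str,
        locus_id: str,
        klass: str,
        fixed_mature: str | None = None,
        check_star: bool = False,
        max_attempts: int = 200,
    ) -> tuple[str, dict]:
        """Plant a hairpin whose stem survives folding in genomic context.

        Wobble placement occasionally lets the folder trade a weakened stem
        pair for a spurious loop-local pair; constructs are therefore
        redrawn (deterministically from the shared generator) until the
        mature arm — and the star arm when requested — classifies TOTAL in
        a ±100 nt window around the locus, the window the discovery branch
        will fold.
        """
        from .structure import OverlapClass, classify_read_overlap, fold_nussinov

        for _ in range(max_attempts):
            mature = fixed_mature or _rand_seq(rng, int(rng.integers(mlo, mhi + 1)))
            loop = int(rng.integers(llo, lhi + 1))
            cand_genome, row = plant_hairpin(
                genome, mature, loop, position, strand,
                config.arm_mismatch_rate, rng, locus_id=locus_id, klass=klass,
                wobble_rate=config.wobble_rate,
            )
            wstart = max(0, row["start"] - 100)
            wend = min(len(cand_genome), row["end"] + 100)
            window = cand_genome[wstart:wend]
            if strand == "-":
                window = revcomp(window)

            def local(a: int, b: int) -> tuple[int, int]:
                return (wend - b, wend - a) if strand == "-" else (a - wstart, b - wstart)

            if config.arm_mismatch_rate > 0:
                return cand_genome, row  # screening only meaningful for clean stems
            structure = fold_nussinov(window)
            ok = classify_read_overlap(
                structure, local(row["mature_start"], row["mature_end"])
            ) is OverlapClass.TOTAL
            if ok and check_star:
                ok = classify_read_overlap(
                    structure, local(row["star_start"], row["star_end"])
                ) is OverlapClass.TOTAL
            if ok:
                return cand_genome, row
        raise RuntimeError(f"could not plant a stable hairpin at {locus_id}")

    # --- known miRNAs ------------------------------------------------------
    family_mature: str | None = None
    for k in range(config.n_known_mirnas):
        i = next(slot_iter)
        if k < 2:
            name = f"syn-mir-1-{k + 1}"
            family = "syn-mir-1"
        else:
            name = f"syn-mir-{k}"
            family = name
        genome, row = plant_screened(
            genome, positions[i], strands[i],
            locus_id=f"known_{name}", klass="known_mirna",
            fixed_mature=family_mature if k < 2 else None,
        )
        if k == 0:
            family_mature = row["mature_seq"]
        mature = row["mature_seq"]
        row["mature_name"] = name
        row["family_key"] = family
        if k == 2:
            row["de_group"] = "dominant"
        elif k in (3, 4):
            row["de_group"] = "up_L1"
        elif k in (5, 6):
            row["de_group"] = "up_L2"
        elif k == 7:
            row["de_group"] = "unique_L1"
        else:
            row["de_group"] = "equal"
        rows.append(row)
        mature_reference.append((name, f"family={family}", mature))
        family_rows.append(
            {"mature_name": name, "precursor_id": name, "family_key": family}
        )

    # --- novel hairpins ----------------------------------------------------
    novel_ids = []
    for k in range(config.n_novel_hairpins):
        i = next(slot_iter)
        genome, row = plant_screened(
            genome, positions[i], strands[i],
            locus_id=f"novel_{k + 1}", klass="novel_hairpin",
            check_star=True,
        )
        row["de_group"] = "equal"
        rows.append(row)
        novel_ids.append(row["locus_id"])
        if k == 0:
            # an "unclassified RNA" database record that is an exact
            # substring of this precursor, mimicking a short-ncRNA hit with
            # high subject coverage
            frag_start = row["start"] + 5
            frag = genome[frag_start:frag_start + 30]
            if row["strand"] == "-":
                frag = revcomp(frag)
            ncrna_db.append(("uncRNA-1", "type=unclassified_RNA", frag))
        if k == config.n_novel_hairpins - 1 and config.n_novel_hairpins > 0:
            # intronic context: gene with terminal exons flanking the locus
            g0, g1 = row["start"] - 400, row["end"] + 400
            ann_rows.append(_feature(config.chrom, "gene", g0, g1, row["strand"], f"gene_intronic_{k}"))
            ann_rows.append(_feature(config.chrom, "exon", g0, g0 + 100, row["strand"], f"exon_l_{k}"))
            ann_rows.append(_feature(config.chrom, "exon", g1 - 100, g1, row["strand"], f"exon_r_{k}"))

    # --- decoys (shuffled hairpins, expressed but structureless) -----------
    def draw_decoy(genome: str, pos: int, strand: str, max_attempts: int = 200):
        """Shuffle a hairpin construct until it truly lacks a stem.

        Shuffling preserves the construct's self-complementary base
        composition, so a draw occasionally re-forms a long duplex over the
        read region; such draws are rejected (a decoy is, by definition, an
        expressed locus without a clean hairpin around its read).
        """
        from .evidence import score_abinitio
        from .structure import fold_nussinov, hairpin_features

        for _ in range(max_attempts):
            mature = _rand_seq(rng, int(rng.integers(mlo, mhi + 1)))
            loop = int(rng.integers(llo, lhi + 1))
            construct = list(mature + _rand_seq(rng, loop) + revcomp(mature))
            rng.shuffle(construct)
            insert = "".join(construct)
            genomic = insert if strand == "+" else revcomp(insert)
            cand = genome[:pos] + genomic + genome[pos + len(insert):]
            wstart = max(0, pos - 100)
            wend = min(len(cand), pos + len(insert) + 100)
            window = cand[wstart:wend]
            if strand == "-":
                window = revcomp(window)
            # the read is insert[:len(mature)] in transcript orientation
            if strand == "-":
                t0 = wend - pos - len(insert)
                read_local = (t0, t0 + len(mature))
            else:
                read_local = (pos - wstart, pos - wstart + len(mature))
            feats = hairpin_features(fold_nussinov(window), read_local)
            if score_abinitio(feats) <= 0.5:
                return cand, insert, mature
        raise RuntimeError("could not draw a structureless decoy")

    for k in range(config.n_decoy_loci):
        i = next(slot_iter)
        pos = positions[i]
        strand = strands[i]
        genome, insert, mature = draw_decoy(genome, pos, strand)
        mlen = len(mature)
        if strand == "+":
            mstart, mend = pos, pos + mlen
            read_seq = insert[:mlen]
        else:
            mstart, mend = pos + len(insert) - mlen, pos + len(insert)
            read_seq = insert[:mlen]
        rows.append({
            "locus_id": f"decoy_{k + 1}", "klass": "decoy", "chrom": config.chrom,
            "start": pos, "end": pos + len(insert), "strand": strand,
            "mature_start": mstart, "mature_end": mend,
            "mature_seq": read_seq, "star_seq": "", "star_start": -1, "star_end": -1,
            "mature_name": "", "family_key": "", "contaminant_class": "",
            "de_group": "equal",
        })
        if k == config.n_decoy_loci - 1 and config.n_decoy_loci > 0:
            g0, g1 = pos - 150, pos + len(insert) + 150
            ann_rows.append(_feature(config.chrom, "gene", g0, g1, strand, f"gene_exonic_{k}"))
            ann_rows.append(_feature(config.chrom, "exon", g0, g1, strand, f"exon_decoy_{k}"))

    # --- contaminant loci --------------------------------------------------
    for k in range(config.n_contaminant_loci):
        i = next(slot_iter)
        klass = _CONTAMINANT_CLASSES[k % len(_CONTAMINANT_CLASSES)]
        length = _CONTAMINANT_LENGTHS[klass]
        seq = _rand_seq(rng, length)
        pos = positions[i]
        strand = "+"
        genome = genome[:pos] + seq + genome[pos + length:]
        rows.append({
            "locus_id": f"contaminant_{klass}_{k + 1}", "klass": "contaminant",
            "chrom": config.chrom, "start": pos, "end": pos + length, "strand": strand,
            "mature_start": pos, "mature_end": pos + length,
            "mature_seq": seq, "star_seq": "", "star_start": -1, "star_end": -1,
            "mature_name": "", "family_key": "", "contaminant_class": klass,
            "de_group": "equal",
        })
        contaminants.append((f"{klass}_{k + 1}", f"class={klass}", seq))
        if klass == "tRNA":
            ann_rows.append(_feature(config.chrom, "tRNA", pos, pos + length, strand, f"trna_{k}"))
            ncrna_db.append((f"db_tRNA_{k + 1}", "type=tRNA", seq))

    # reference-typed entries for the ncRNA database
    for name, _, seq in mature_reference[:3]:
        ncrna_db.append((f"db_{name}", "type=miRNA", seq))
    ncrna_db.append(("db_snoRNA_1", "type=snoRNA", _rand_seq(rng, 90)))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth["chrom"] = config.chrom
    _check_non_overlapping(truth)

    annotation = pd.DataFrame(
        ann_rows,
        columns=["seqid", "source", "type", "start0", "end0", "score", "strand", "phase", "attributes"],
    )
    family_map = pd.DataFrame(family_rows, columns=["mature_name", "precursor_id", "family_key"])
    return Fixture(
        config=config, genome=genome, truth=truth,
        mature_reference=mature_reference, family_map=family_map,
        contaminants=contaminants, ncrna_db=ncrna_db, annotation=annotation,
    )


def _feature(chrom: str, ftype: str, start: int, end: int, strand: str, fid: str) -> dict:
    return {
        "seqid": chrom, "source": "mirquest_sim", "type": ftype,
        "start0": start, "end0": end, "score": ".", "strand": strand,
        "phase": ".", "attributes": gff3_attributes({"ID": fid}),
    }


def _check_non_overlapping(truth: pd.DataFrame) -> None:
    ordered = truth.sort_values("start")
    prev_end = -1
    for _, row in ordered.iterrows():
        if row["start"] < prev_end:
            raise ValueError("planted loci overlap; increase genome_length")
        prev_end = row["end"]


def _expression_multiplier(de_group: str, library: str) -> float:
    if de_group == "dominant":
        return 10.0
    if de_group == "up_L1":
        return 4.0 if library == "L1" else 1.0
    if de_group == "up_L2":
        return 4.0 if library == "L2" else 1.0
    if de_group == "unique_L1":
        return 1.0 if library == "L1" else 0.0
    return 1.0


def _jitter_probs(max_jitter: int) -> np.ndarray:
    w = np.array(_JITTER_WEIGHTS[: max_jitter + 1], dtype=float)
    return w / w.sum()


def simulate_reads(
    fixture: Fixture, config: SimConfig | None = None
) -> tuple[list[tuple[str, str, str]], dict[str, str]]:
    """Draw reads for every truth locus and library.

    Per locus and library the copy number is Poisson with mean
    ``expression_mean_per_locus`` x the locus multiplier (or the rounded
    mean in fixed-count mode).  miRNA-like loci emit their mature arm (and,
    for novel hairpins, the star arm at ``star_fraction`` of the mature
    mean); contaminant loci emit random 18-30 nt fragments of their
    sequence.  Ends are trimmed by 0-``read_end_jitter`` nt (weights favour
    canonical ends) and substitution errors applied at ``error_rate``.

    Returns (reads, read_truth) with reads as (read_id, library, sequence)
    and stores both on the fixture.  The drawn copy number per locus and
    library is recorded in truth columns ``drawn_<lib>``.
    """
    if config is None:
        config = fixture.config
    rng = np.random.default_rng(config.seed + 1)
    jp = _jitter_probs(config.read_end_jitter)
    reads: list[tuple[str, str, str]] = []
    read_truth: dict[str, str] = {}
    drawn: dict[str, dict[str, int]] = {lib: {} for lib in config.libraries}

    def emit(locus_id: str, library: str, template: str, count: int, is_fragment: bool, serial_start: int) -> int:
        serial = serial_start
        for _ in range(count):
            if is_fragment:
                flen = int(rng.integers(18, min(31, len(template) + 1)))
                off = int(rng.integers(0, len(template) - flen + 1))
                seq = template[off:off + flen]
            else:
                t5 = int(rng.choice(len(jp), p=jp))
                t3 = int(rng.choice(len(jp), p=jp))
                seq = template[t5: len(template) - t3 if t3 else len(template)]
            seq = _mutate(seq, config.error_rate, rng)
            rid = f"{library}|{locus_id}|{serial}"
            reads.append((rid, library, seq))
            read_truth[rid] = locus_id
            serial += 1
        return serial

    for _, row in fixture.truth.iterrows():
        locus_id = row["locus_id"]
        for library in config.libraries:
            mult = _expression_multiplier(row["de_group"], library)
            mean = config.expression_mean_per_locus * mult
            if config.fixed_counts:
                count = int(round(mean))
            else:
                count = int(rng.poisson(mean)) if mean > 0 else 0
            serial = emit(
                locus_id, library, row["mature_seq"], count,
                is_fragment=(row["klass"] == "contaminant"), serial_start=0,
            )
            total = count
            if row["klass"] == "novel_hairpin" and row["star_seq"]:
                smean = mean * config.star_fraction
                if config.fixed_counts:
                    scount = int(round(smean))
                else:
                    scount = int(rng.poisson(smean)) if smean > 0 else 0
                emit(locus_id, library, row["star_seq"], scount, False, serial)
                total += scount
            drawn[library][locus_id] = total

    for library in config.libraries:
        fixture.truth[f"expected_{library}"] = [
            config.expression_mean_per_locus
            * _expression_multiplier(g, library)
            * (1 + (config.star_fraction if k == "novel_hairpin" else 0))
            for g, k in zip(fixture.truth["de_group"], fixture.truth["klass"])
        ]
        fixture.truth[f"drawn_{library}"] = [
            drawn[library].get(lid, 0) for lid in fixture.truth["locus_id"]
        ]
    fixture.reads = reads
    fixture.read_truth = read_truth
    return reads, read_truth


def make_fixture(config: SimConfig, out_dir: str | Path) -> Fixture:
    """Generate the full study bundle and write it to ``out_dir``.

    Writes genome FASTA, mature-miRNA reference FASTA, annotation GFF3,
    family map TSV, contaminant FASTA, ncRNA database FASTA, one FASTQ of
    reads for all libraries, and the truth TSV, plus a JSON manifest with
    per-file SHA-256 checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = build_truth(config)
    simulate_reads(fixture, config)

    paths = {
        "genome": out / "genome.fa",
        "mature": out / "mature.fa",
        "annotation": out / "annotation.gff3",
        "families": out / "families.tsv",
        "contaminants": out / "contaminants.fa",
        "ncrna_db": out / "ncrna_db.fa",
        "reads": out / "reads.fastq",
        "truth": out / "truth.tsv",
    }
    write_fasta([(config.chrom, "synthetic genome", fixture.genome)], paths["genome"])
    write_fasta(fixture.mature_reference, paths["mature"])
    write_gff3(fixture.annotation, paths["annotation"])
    fixture.family_map.to_csv(paths["families"], sep="\t", index=False)
    write_fasta(fixture.contaminants, paths["contaminants"])
    write_fasta(fixture.ncrna_db, paths["ncrna_db"])
    write_fastq([(rid, seq) for rid, _lib, seq in fixture.reads], paths["reads"])
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    fixture.paths = paths
    fixture.manifest = write_manifest(
        paths, out / "manifest.json",
        extra={"seed": config.seed, "n_reads": len(fixture.reads)},
    )
    return fixture
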