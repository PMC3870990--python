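"""End-to-end orchestration of the two analysis branches.

Branch one (quantification): filter contaminants, match reads to the
mature reference under the mismatch budget, collapse multi-hits to
families, count, max-normalize, and compare libraries (2-fold differential
calls, uniquely expressed miRNAs, top-N abundance, common-miRNA
percentages).  Branch two (discovery): take the reads that matched
nothing, keep abundant short ones, map them exactly to the genome, cluster,
extend ±100 nt into putative precursors, merge adjacent two-arm loci, fold,
collect similarity/structural/ab-initio evidence and integrate verdict
tiers.  A ledger accounts for every read copy of every library.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .discover import (
    CandidateLocus,
    assign_genomic_context,
    cluster_by_position,
    extend_cluster,
    map_reads_exact,
    merge_adjacent_candidates,
    select_discovery_reads,
)
from .evidence import (
    ABINITIO_CUTOFF,
    EvidenceRecord,
    exclude_false_positives,
    integrate_evidence,
    load_ncrna_db,
    parse_hhmmir_scores,
    parse_infernal_tblout,
    score_abinitio,
    similarity_search,
)
from .expression import (
    ExpressionProfile,
    call_differential,
    common_mirna_percentage,
    normalize_max,
    top_expressed,
    unique_expressed,
)
from .io import read_fasta, read_gff3, write_fasta, write_gff3, write_manifest
from .quantify import (
    ReadRecord,
    assign_read,
    filter_contaminants,
    load_contaminants,
    load_mature_reference,
    load_reads,
    match_mature,
    quantify,
)
from .structure import hairpin_features, fold_nussinov

__all__ = ["PipelineConfig", "run_quantify", "run_discover", "write_reports"]


@dataclass
class PipelineConfig:
    """All thresholds and file paths of the pipeline.

    Numeric defaults are the published operating points of the protocol:
    2-fold differential expression, >= 10 copies for unique calls and for
    discovery reads, < 35 nt discovery reads, a 5-hit single-family
    collapse cap, ±100 nt precursor extension, similarity retention at 80%
    identity / 80% coverage with word size 6, structural-search bit-score
    cutoff 25 and ab-initio cutoff 0.71.  ``max_evalue`` bounds the proxy
    E-value and is deliberately permissive: the proxy does not reproduce a
    real aligner's statistics, so identity and coverage are the decisive
    similarity filters.
    """

    # inputs
    reads: str = ""
    genome: str = ""
    mature: str = ""
    families: str | None = None
    contaminants: str | None = None
    ncrna_db: str | None = None
    annotation: str | None = None
    infernal_tblout: str | None = None
    hhmmir_scores: str | None = None
    trna_calls: str | None = None
    # quantification
    contaminant_max_mismatch: int = 0
    max_mismatch: int = 2
    max_shift: int = 2
    max_hits: int = 5
    cap_on: str = "hits"
    # expression
    min_fold: float = 2.0
    min_unique_count: int = 10
    norm_scale: float = 1.0
    # discovery
    min_copies: int = 10
    copies_inclusive: bool = True
    max_len: int = 35
    max_loci: int = 5
    max_gap: int = 10
    flank: int = 100
    max_separation: int = 50
    # evidence
    word_size: int = 6
    min_identity: float = 80.0
    min_coverage: float = 80.0
    max_evalue: float = 10.0
    infernal_cutoff: float = 25.0
    abinitio_cutoff: float = ABINITIO_CUTOFF
    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if not value:
                raise FileNotFoundError(f"config field {name!r} is required but unset")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name} file not found: {value}")


@dataclass
class QuantifyResults:
    profiles: dict[str, ExpressionProfile]
    ledgers: dict[str, dict[str, int]]
    unmatched: dict[str, list[ReadRecord]]
    contaminant_classes: dict[str, dict[str, int]]
    differential: pd.DataFrame | None = None
    unique: dict[str, set[str]] = field(default_factory=dict)
    top: dict[str, tuple[pd.DataFrame, float]] = field(default_factory=dict)
    comparison: pd.DataFrame | None = None


@dataclass
class DiscoverResults:
    candidates: list[CandidateLocus]
    records: list[EvidenceRecord]
    dropped_log: pd.DataFrame
    per_library_counts: dict[str, dict[str, int]]  # candidate_id -> lib -> copies
    table: pd.DataFrame | None = None


def run_quantify(config: PipelineConfig) -> QuantifyResults:
    """Run the quantification branch for every library in the reads file."""
    config.require("reads", "mature")
    reads = load_reads(config.reads)
    references = load_mature_reference(config.mature, config.families)
    contaminant_db = load_contaminants(config.contaminants) if config.contaminants else []

    by_lib: dict[str, list[ReadRecord]] = defaultdict(list)
    for read in reads:
        by_lib[read.library_id].append(read)

    profiles: dict[str, ExpressionProfile] = {}
    ledgers: dict[str, dict[str, int]] = {}
    unmatched: dict[str, list[ReadRecord]] = {}
    cont_classes: dict[str, dict[str, int]] = {}
    from .quantify import AssignmentResult

    for lib in sorted(by_lib):
        lib_reads = by_lib[lib]
        kept, removed = filter_contaminants(
            lib_reads, contaminant_db, config.contaminant_max_mismatch
        )
        assignments = [
            AssignmentResult(read, "contaminant", contaminant_class=klass)
            for read, klass in removed
        ]
        un: list[ReadRecord] = []
        for read in kept:
            hits = match_mature(read, references, config.max_mismatch, config.max_shift)
            res = assign_read(read, hits, config.max_hits, config.cap_on)
            assignments.append(res)
            if res.status == "unmatched":
                un.append(read)
        counts, ledger = quantify(assignments, lib)
        profiles[lib] = normalize_max(
            ExpressionProfile(lib, counts), scale=config.norm_scale
        )
        ledgers[lib] = ledger
        unmatched[lib] = un
        per_class: dict[str, int] = defaultdict(int)
        for read, klass in removed:
            per_class[klass] += read.count
        cont_classes[lib] = dict(per_class)

    results = QuantifyResults(profiles, ledgers, unmatched, cont_classes)
    libs = sorted(profiles)
    if len(libs) >= 2:
        a, b = libs[0], libs[1]
        results.differential = call_differential(
            profiles[a], profiles[b], min_fold=config.min_fold
        )
        ua, ub = unique_expressed(profiles[a], profiles[b], config.min_unique_count)
        results.unique = {a: ua, b: ub}
        comparison = []
        for sample in libs:
            for ref in libs:
                if sample == ref:
                    continue
                comparison.append(
                    {
                        "sample": sample,
                        "reference": ref,
                        "total_mirnas": len(profiles[sample].detected()),
                        "common_mirnas": len(
                            profiles[sample].detected() & profiles[ref].detected()
                        ),
                        "pct_common": common_mirna_percentage(
                            profiles[sample].detected(), profiles[ref].detected()
                        ),
                    }
                )
        results.comparison = pd.DataFrame(comparison)
    for lib in libs:
        results.top[lib] = top_expressed(profiles[lib], n=10)
    return results


def _pool_unmatched(
    unmatched: dict[str, list[ReadRecord]]
) -> tuple[list[ReadRecord], dict[str, dict[str, int]]]:
    """Pool unmatched reads across libraries by sequence, keeping per-library copies."""
    total: dict[str, int] = defaultdict(int)
    per_lib: dict[str, dict[str, int]] = defaultdict(dict)
    for lib, reads in sorted(unmatched.items()):
        for read in reads:
            total[read.sequence] += read.count
            per_lib[read.sequence][lib] = per_lib[read.sequence].get(lib, 0) + read.count
    pooled = [
        ReadRecord(f"pool_u{idx:06d}", seq, cnt, "pooled")
        for idx, (seq, cnt) in enumerate(sorted(total.items()), start=1)
    ]
    return pooled, dict(per_lib)


def run_discover(
    config: PipelineConfig, quantify_results: QuantifyResults
) -> DiscoverResults:
    """Run the discovery branch on the reads that matched no known miRNA."""
    config.require("genome")
    genome = {rid: seq for rid, _desc, seq in read_fasta(config.genome)}
    annotation = read_gff3(config.annotation) if config.annotation else None

    pooled, per_lib_seq = _pool_unmatched(quantify_results.unmatched)
    selected = select_discovery_reads(
        pooled, config.min_copies, config.max_len, config.copies_inclusive
    )
    placements, dropped = map_reads_exact(selected, genome, config.max_loci)
    clusters = cluster_by_position(placements, config.max_gap)
    candidates = [
        extend_cluster(cluster, genome, config.flank, candidate_id=f"cand{i + 1}")
        for i, cluster in enumerate(clusters)
    ]
    for cand in candidates:
        cand.genomic_context = assign_genomic_context(cand, annotation)
    candidates = merge_adjacent_candidates(
        candidates, genome, config.max_separation
    )
    for cand in candidates:
        cand.genomic_context = assign_genomic_context(cand, annotation)

    ncrna_db = load_ncrna_db(config.ncrna_db) if config.ncrna_db else []
    family_by_cand: dict[str, list] = defaultdict(list)
    if config.infernal_tblout:
        for hit in parse_infernal_tblout(config.infernal_tblout, config.infernal_cutoff):
            family_by_cand[hit.candidate_id].append(hit)
    external_scores = (
        parse_hhmmir_scores(config.hhmmir_scores, config.abinitio_cutoff)
        if config.hhmmir_scores
        else {}
    )
    trna_calls: set[str] = set()
    if config.trna_calls:
        trna_calls = {
            line.split()[0]
            for line in Path(config.trna_calls).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }

    structures = {
        cand.candidate_id: fold_nussinov(cand.precursor_sequence)
        for cand in candidates
    }
    sim_hits = {
        cand.candidate_id: (
            similarity_search(
                cand, ncrna_db, config.word_size, config.min_identity,
                config.min_coverage, config.max_evalue,
            )
            if ncrna_db
            else []
        )
        for cand in candidates
    }
    kept, excluded = exclude_false_positives(candidates, sim_hits, trna_calls)
    reason_by_id = {cand.candidate_id: reason for cand, reason in excluded}

    per_library_counts: dict[str, dict[str, int]] = {}
    libs = sorted(quantify_results.profiles)
    records: list[EvidenceRecord] = []
    for cand in candidates:
        structure = structures[cand.candidate_id]
        lib_counts: dict[str, int] = {lib: 0 for lib in libs}
        for mr, _off in cand.reads:
            for lib, cnt in per_lib_seq.get(mr.read.sequence, {}).items():
                lib_counts[lib] = lib_counts.get(lib, 0) + cnt
        per_library_counts[cand.candidate_id] = lib_counts
        norm_counts = {}
        for lib in libs:
            prof = quantify_results.profiles[lib]
            lib_max = max(prof.raw.values()) if prof.raw else 0
            norm_counts[lib] = (
                lib_counts.get(lib, 0) / lib_max * config.norm_scale if lib_max else 0.0
            )
        if cand.candidate_id in external_scores:
            ab_score = external_scores[cand.candidate_id][0]
        else:
            reads_present = [
                iv for iv in cand.read_intervals() if iv[1] <= len(structure)
            ]
            feats = hairpin_features(
                structure, reads_present[0] if reads_present else None
            )
            ab_score = score_abinitio(feats)
        records.append(
            integrate_evidence(
                cand,
                structure,
                sim_hits.get(cand.candidate_id, []),
                family_by_cand.get(cand.candidate_id, []),
                ab_score,
                norm_counts,
                reason_by_id.get(cand.candidate_id),
                config.abinitio_cutoff,
            )
        )

    results = DiscoverResults(candidates, records, dropped, per_library_counts)
    results.table = evidence_table(records)
    return results


def evidence_table(records: list[EvidenceRecord]) -> pd.DataFrame:
    """Flatten evidence records into the report table (one row per candidate)."""
    rows = []
    for rec in records:
        sim = rec.similarity_hits[0] if rec.similarity_hits else None
        fam = rec.family_hits[0] if rec.family_hits else None
        row = {
            "candidate_id": rec.candidate_id,
            "genomic_location": rec.genomic_context,
            "similarity_summary": (
                f"subject={sim.subject_id};type={sim.subject_type};"
                f"QueryCov={sim.query_coverage:.0f}%;SbjCov={sim.subject_coverage:.0f}%;"
                f"Id={sim.identity:.0f}%"
                if sim
                else "-"
            ),
            "abinitio_score": round(rec.abinitio_score, 3) if rec.abinitio_score is not None else None,
            "read_overlaps_helix": rec.read_overlap.value,
            "energy": round(rec.energy, 2),
            "energy_is_proxy": rec.energy_is_proxy,
            "family": fam.family_id if fam else "-",
            "family_accession": fam.accession if fam else "-",
            "family_strand": fam.strand if fam else "-",
            "family_bit_score": fam.bit_score if fam else None,
            "family_start": fam.start if fam else None,
            "family_end": fam.end if fam else None,
            "verdict_tier": rec.verdict_tier,
            "exclusion_reason": rec.exclusion_reason or "-",
        }
        for lib, val in sorted(rec.normalized_counts.items()):
            row[f"norm_{lib}"] = round(val, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(
    quantify_results: QuantifyResults,
    discover_results: DiscoverResults | None,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write all report tables, exports and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ledger_rows = []
    for lib in sorted(quantify_results.ledgers):
        ledger = quantify_results.ledgers[lib]
        for status in sorted(ledger):
            ledger_rows.append({"library": lib, "status": status, "copies": ledger[status]})
    paths["ledger"] = out / "ledger.tsv"
    pd.DataFrame(ledger_rows).to_csv(paths["ledger"], sep="\t", index=False)

    for lib, profile in sorted(quantify_results.profiles.items()):
        p = out / f"counts_{lib}.tsv"
        profile.to_frame().to_csv(p, sep="\t", index=False)
        paths[f"counts_{lib}"] = p

    if quantify_results.differential is not None:
        paths["differential"] = out / "differential.tsv"
        quantify_results.differential.to_csv(paths["differential"], sep="\t", index=False)
    if quantify_results.unique:
        rows = [
            {"library": lib, "label": label}
            for lib in sorted(quantify_results.unique)
            for label in sorted(quantify_results.unique[lib])
        ]
        paths["unique"] = out / "unique.tsv"
        pd.DataFrame(rows, columns=["library", "label"]).to_csv(
            paths["unique"], sep="\t", index=False
        )
    top_rows = []
    for lib, (df, frac) in sorted(quantify_results.top.items()):
        for _, row in df.iterrows():
            top_rows.append({"library": lib, **row.to_dict(), "cumulative_fraction_top_n": round(frac, 4)})
    if top_rows:
        paths["top"] = out / "top_expressed.tsv"
        pd.DataFrame(top_rows).to_csv(paths["top"], sep="\t", index=False)
    if quantify_results.comparison is not None:
        paths["comparison"] = out / "comparison.tsv"
        quantify_results.comparison.to_csv(paths["comparison"], sep="\t", index=False)

    if discover_results is not None:
        paths["candidates"] = out / "candidates.tsv"
        discover_results.table.to_csv(paths["candidates"], sep="\t", index=False)
        paths["dropped"] = out / "discovery_dropped.tsv"
        discover_results.dropped_log.to_csv(paths["dropped"], sep="\t", index=False)
        # BED6
        paths["bed"] = out / "candidates.bed"
        with open(paths["bed"], "w") as fh:
            for cand in discover_results.candidates:
                fh.write(
                    f"{cand.chrom}\t{cand.start}\t{cand.end}\t{cand.candidate_id}\t0\t{cand.strand}\n"
                )
        paths["fasta"] = out / "candidates.fa"
        write_fasta(
            [
                (
                    cand.candidate_id,
                    "offsets=" + ",".join(str(off) for _mr, off in cand.reads),
                    cand.precursor_sequence,
                )
                for cand in discover_results.candidates
            ],
            paths["fasta"],
        )
        paths["gff3"] = out / "candidates.gff3"
        feats = pd.DataFrame(
            [
                {
                    "seqid": cand.chrom, "source": "mirquest", "type": "miRNA_candidate",
                    "start0": cand.start, "end0": cand.end, "score": ".",
                    "strand": cand.strand, "phase": ".",
                    "attributes": f"ID={cand.candidate_id};tier={rec.verdict_tier}",
                }
                for cand, rec in zip(
                    discover_results.candidates, discover_results.records
                )
            ]
        )
        write_gff3(feats, paths["gff3"])

    manifest_path = out / "run_manifest.json"
    write_manifest(
        paths,
        manifest_path,
        extra={
            "config_hash": config.config_hash(),
            "tool_version": __version__,
            "seed": config.seed,
        },
    )
    paths["manifest"] = manifest_path
    return paths
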