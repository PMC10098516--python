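"""Amplicon sequence processing: filter, demultiplex, dereplicate, cluster.

Re-implements the classical tagged-amplicon workflow used for fungal ITS2
metabarcoding: reads carry a sample-identifying tag pair and the fITS7/ITS4
primers at their ends; they are quality-filtered (length > 100 bp after
tag/primer removal, mean Phred > 20, every base > 3, forward-primer identity
> 0.90, both tags intact — all strict inequalities), demultiplexed by exact
tag-pair lookup, dereplicated into genotypes with global singletons removed,
and single-linkage clustered into species hypotheses at 98.5% pairwise
identity.  Identity is defined as matching columns over alignment length
under a unit-cost global alignment, so gap columns count against identity.

Cluster representatives (the most abundant member genotype, ties broken by
lexicographically smallest sequence) are compared to a labelled reference to
assign genus and ectomycorrhizal-guild status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .synthdata import FWD_PRIMER, REV_PRIMER, _revcomp

__all__ = [
    "ReadRecord",
    "FilterParams",
    "SpeciesHypothesis",
    "read_fastq",
    "parse_reads",
    "filter_reads",
    "demultiplex",
    "dereplicate_and_drop_singletons",
    "pairwise_identity",
    "cluster_single_linkage",
    "assign_taxonomy",
    "read_reference_fasta",
    "read_tag_map",
]


# ---------------------------------------------------------------------------
# records and parsing
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """One tagged amplicon read after structural parsing.

    ``sequence``/``quality`` cover the biological template only (tags and
    primers removed); tag ids are None when the observed tag is not in the
    tag set.
    """

    read_id: str
    sequence: str
    quality: np.ndarray
    fwd_tag: str | None
    rev_tag: str | None
    primer_identity: float
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass
class FilterParams:
    """Quality-filter thresholds; a read must beat every one strictly."""

    min_length: int = 100
    min_mean_quality: float = 20.0
    min_base_quality: float = 3.0
    min_primer_identity: float = 0.90
    require_both_tags: bool = True

    def __post_init__(self) -> None:
        for name in ("min_length", "min_mean_quality", "min_base_quality", "min_primer_identity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def read_fastq(path) -> list[tuple[str, str, np.ndarray]]:
    """Load Phred+33 FASTQ as (id, sequence, qualities) tuples."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            q = np.array(rec.letter_annotations["phred_quality"], dtype=int)
            out.append((rec.id, str(rec.seq), q))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc
    return out


def parse_reads(
    raw: list[tuple[str, str, np.ndarray]],
    tag_map: pd.DataFrame,
    fwd_primer: str = FWD_PRIMER,
    rev_primer: str = REV_PRIMER,
) -> list[ReadRecord]:
    """Structurally decompose raw reads into tag / primer / template.

    Tags are fixed-length and flank the read (the reverse tag reverse-
    complemented at the 3' end); they are recognised by exact membership in
    the tag map's tag sets — no error correction.  Forward-primer identity is
    the match fraction over the primer-length window after the forward tag.
    """
    fwd_tags = set(tag_map["fwd_tag"])
    rev_tags = set(tag_map["rev_tag"])
    tag_len = len(next(iter(fwd_tags))) if fwd_tags else 0
    if any(len(t) != tag_len for t in fwd_tags | rev_tags):
        raise ValueError("all tags must share one length")
    records = []
    for read_id, seq, qual in raw:
        if len(seq) < 2 * tag_len + len(fwd_primer) + len(rev_primer) + 1:
            records.append(
                ReadRecord(read_id, "", np.empty(0, dtype=int), None, None, 0.0)
            )
            continue
        f_obs = seq[:tag_len]
        r_obs = _revcomp(seq[-tag_len:]) if tag_len else ""
        primer_obs = seq[tag_len : tag_len + len(fwd_primer)]
        ident = float(np.mean([a == b for a, b in zip(primer_obs, fwd_primer)]))
        start = tag_len + len(fwd_primer)
        stop = len(seq) - tag_len - len(rev_primer)
        records.append(
            ReadRecord(
                read_id=read_id,
                sequence=seq[start:stop],
                quality=np.asarray(qual[start:stop], dtype=int),
                fwd_tag=f_obs if f_obs in fwd_tags else None,
                rev_tag=r_obs if r_obs in rev_tags else None,
                primer_identity=ident,
            )
        )
    return records


# ---------------------------------------------------------------------------
# filtering and demultiplexing
# ---------------------------------------------------------------------------

def filter_reads(
    reads: list[ReadRecord], params: FilterParams | None = None
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Apply the strict quality thresholds; log the first failure per read.

    Returns (retained, rejection_log); the log has columns ``read_id`` and
    ``reason`` ∈ {length, mean_quality, base_quality, primer, tags}.
    Criteria are checked in that order and lengths refer to the template
    after tag/primer removal.
    """
    params = params or FilterParams()
    kept, rejected = [], []

    def _reason(r: ReadRecord) -> str | None:
        if len(r.sequence) <= params.min_length:
            return "length"
        if float(np.mean(r.quality)) <= params.min_mean_quality:
            return "mean_quality"
        if float(np.min(r.quality)) <= params.min_base_quality:
            return "base_quality"
        if r.primer_identity <= params.min_primer_identity:
            return "primer"
        if params.require_both_tags and (r.fwd_tag is None or r.rev_tag is None):
            return "tags"
        return None

    for r in reads:
        reason = _reason(r)
        if reason is None:
            kept.append(r)
        else:
            rejected.append({"read_id": r.read_id, "reason": reason})
    return kept, pd.DataFrame(rejected, columns=["read_id", "reason"])


def demultiplex(
    reads: list[ReadRecord], tag_map: pd.DataFrame
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Assign reads to samples by exact tag-pair lookup.

    Returns (assigned, unassigned); reads whose tag pair is absent from the
    map (including reads with a missing tag) land in the unassigned bin
    rather than being dropped silently.
    """
    pairs: dict[tuple[str, str], str] = {}
    for _, row in tag_map.iterrows():
        key = (row["fwd_tag"], row["rev_tag"])
        if key in pairs:
            raise ValueError(f"duplicate tag pair {key} in tag map")
        pairs[key] = row["sample_id"]
    assigned, unassigned = [], []
    for r in reads:
        sample = pairs.get((r.fwd_tag, r.rev_tag)) if r.fwd_tag and r.rev_tag else None
        if sample is None:
            unassigned.append(r)
        else:
            r.sample_id = sample
            assigned.append(r)
    return assigned, unassigned


def dereplicate_and_drop_singletons(reads: list[ReadRecord]) -> pd.DataFrame:
    """Collapse identical template sequences into genotypes.

    Returns a genotypes x samples count DataFrame indexed by sequence;
    genotypes seen exactly once across the whole data set (global
    singletons) are removed.
    """
    if not reads:
        return pd.DataFrame()
    counts: dict[str, dict[str, int]] = {}
    for r in reads:
        if r.sample_id is None:
            raise ValueError("reads must be demultiplexed before dereplication")
        counts.setdefault(r.sequence, {}).setdefault(r.sample_id, 0)
        counts[r.sequence][r.sample_id] += 1
    table = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    table.index.name = "sequence"
    return table[table.sum(axis=1) > 1]


# ---------------------------------------------------------------------------
# pairwise identity and clustering
# ---------------------------------------------------------------------------

def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity under unit mismatch/gap costs.

    Identity is ``1 - editDistance / max(|a|, |b|)``: every substitution or
    gap counts one column against identity, and the alignment length is
    fixed to the longer sequence so that equally optimal alignments (which
    can trade a substitution for an insertion/deletion pair) all yield the
    same value.  Symmetric; identity(s, s) = 1.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    dist = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(seq_a), len(seq_b))


@dataclass
class SpeciesHypothesis:
    """A single-linkage cluster of genotypes — the operational species unit."""

    sh_id: str
    members: list[str]  # genotype sequences
    counts: pd.Series  # per-sample counts summed over members
    representative: str
    taxon: str | None = None
    genus: str = "unclassified"
    is_emf: bool = False
    best_identity: float = 0.0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_single_linkage(
    genotypes: pd.DataFrame, threshold: float = 0.985
) -> list[SpeciesHypothesis]:
    """Single-linkage clustering of genotypes at a pairwise-identity threshold.

    Two genotypes share a species hypothesis iff they are connected by a
    chain of pairwise identities >= threshold (transitive closure).  A cheap
    length-difference bound prunes pairs that cannot reach the threshold
    before any alignment is computed; the result is exactly the connected
    components of the >=-threshold identity graph.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    seqs = list(genotypes.index)
    n = len(seqs)
    uf = _UnionFind(n)
    lengths = np.array([len(s) for s in seqs])
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            # |len_a - len_b| gaps are unavoidable: identity <= min/max length
            la, lb = lengths[i], lengths[j]
            if min(la, lb) / max(la, lb) < threshold:
                continue
            if pairwise_identity(seqs[i], seqs[j]) >= threshold:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    shs = []
    # deterministic ordering: by first member's position in the input table
    for k, (_, idxs) in enumerate(sorted(groups.items(), key=lambda kv: min(kv[1])), start=1):
        members = [seqs[i] for i in idxs]
        totals = genotypes.iloc[idxs].sum(axis=1)
        best = min(members, key=lambda s: (-totals[s], s))
        shs.append(
            SpeciesHypothesis(
                sh_id=f"SH{k:04d}",
                members=members,
                counts=genotypes.iloc[idxs].sum(axis=0),
                representative=best,
            )
        )
    return shs


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def read_reference_fasta(path) -> pd.DataFrame:
    """Reference with ``>taxon|genus|guild`` headers -> DataFrame
    (taxon, genus, is_emf, sequence), in file order."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(f"reference header {rec.id!r} is not taxon|genus|guild")
        taxon, genus, guild = parts
        rows.append(
            {
                "taxon": taxon,
                "genus": genus,
                "is_emf": guild.upper() == "EMF",
                "sequence": str(rec.seq),
            }
        )
    if not rows:
        raise ValueError(f"reference FASTA {path} is empty")
    return pd.DataFrame(rows)


def assign_taxonomy(
    shs: list[SpeciesHypothesis],
    reference: pd.DataFrame,
    min_identity: float = 0.985,
) -> list[SpeciesHypothesis]:
    """Label each species hypothesis with its best-identity reference.

    The representative sequence is aligned to every reference; the best hit
    assigns genus and guild if its identity >= ``min_identity``, otherwise
    the cluster stays "unclassified" and non-ectomycorrhizal.  Exact ties go
    to the reference that appears first in the file.
    """
    for sh in shs:
        best_i, best_row = 0.0, None
        for _, row in reference.iterrows():
            ident = pairwise_identity(sh.representative, row["sequence"])
            if ident > best_i:  # strict: first-in-file wins ties
                best_i, best_row = ident, row
        sh.best_identity = best_i
        if best_row is not None and best_i >= min_identity:
            sh.taxon = best_row["taxon"]
            sh.genus = best_row["genus"]
            sh.is_emf = bool(best_row["is_emf"])
        else:
            sh.taxon = None
            sh.genus = "unclassified"
            sh.is_emf = False
    return shs


def read_tag_map(path) -> pd.DataFrame:
    """Load a two-column tag map TSV (sample_id, fwd:rev) into long form."""
    raw = pd.read_csv(path, sep="\t")
    tags = raw["tags"].str.split(":", expand=True)
    return pd.DataFrame(
        {"sample_id": raw["sample_id"], "fwd_tag": tags[0], "rev_tag": tags[1]}
    )


def sh_count_table(shs: list[SpeciesHypothesis]) -> pd.DataFrame:
    """Samples x species-hypothesis count matrix from annotated clusters.

    Columns are labelled by assigned taxon where available, else sh_id.
    """
    cols = {}
    for sh in shs:
        label = sh.taxon if sh.taxon else sh.sh_id
        cols[label] = sh.counts
    table = pd.DataFrame(cols).fillna(0).astype(np.int64)
    table.index.name = "sample_id"
    return table
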