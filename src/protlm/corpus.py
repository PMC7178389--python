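"""Sequence/cluster I/O and cluster-aware dataset protocols.

Protein benchmark construction is dominated by one concern: near-duplicate
sequences (members of the same identity cluster, e.g. UniRef50 or CD-HIT
output) must not span the train/test boundary, otherwise test performance
measures memorization rather than generalization.  This module implements

* ``ClusterTable`` / ``DatasetSplit`` containers,
* ``make_split`` — random or cluster-aware 90:5:5-style partitioning,
* ``expand_members`` — redundancy modes: train on all cluster members or on
  representatives only, while validation/test always contain representatives,
* ``subsample_training`` — nested training-set-size reduction at fixed
  validation/test sets,
* ``read_corpus`` / ``write_corpus`` — FASTA + TSV plumbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .vocab import AminoAcidVocabulary, ProteinRecord, normalize_sequence

RANDOM = "random"
CLUSTER = "cluster"
ALL_MEMBERS = "all_members"
REPRESENTATIVES_ONLY = "representatives_only"


class CorpusFormatError(ValueError):
    """Malformed or inconsistent corpus files."""


@dataclass
class ClusterTable:
    """Sequence → cluster map plus one designated representative per cluster."""

    member_of: dict[str, str]
    representative: dict[str, str]

    def __post_init__(self):
        members = self.members_by_cluster()
        for cid, rep in self.representative.items():
            if rep not in self.member_of or self.member_of[rep] != cid:
                raise CorpusFormatError(
                    f"representative {rep!r} is not a member of cluster {cid!r}"
                )
        for cid in members:
            if not members[cid]:
                raise CorpusFormatError(f"cluster {cid!r} is empty")

    def members_by_cluster(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, cid in self.member_of.items():
            out.setdefault(cid, []).append(sid)
        for cid in out:
            out[cid].sort()
        return out

    @property
    def cluster_ids(self) -> list[str]:
        return sorted({*self.member_of.values()})

    @classmethod
    def singletons(cls, seq_ids) -> "ClusterTable":
        """Each sequence its own cluster and representative."""
        return cls(
            member_of={s: s for s in seq_ids},
            representative={s: s for s in seq_ids},
        )


@dataclass
class DatasetSplit:
    """Disjoint train/valid/test sequence-id sets."""

    train: set[str]
    valid: set[str]
    test: set[str]
    mode: str
    ratios: tuple[float, float, float]

    def __post_init__(self):
        parts = [self.train, self.valid, self.test]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("split partitions overlap")


def _largest_remainder_counts(n: int, ratios) -> list[int]:
    raw = [r * n for r in ratios]
    counts = [math.floor(x) for x in raw]
    rem = n - sum(counts)
    # assign leftovers to the largest fractional parts, ties by position
    order = sorted(range(len(ratios)), key=lambda i: (counts[i] - raw[i], i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def make_split(
    clusters: ClusterTable,
    ratios: tuple[float, float, float] = (0.9, 0.05, 0.05),
    mode: str = CLUSTER,
    seed: int = 0,
) -> DatasetSplit:
    """Partition sequences into train/valid/test.

    ``cluster`` mode assigns whole clusters to partitions (ratio targets apply
    to cluster counts); ``random`` mode shuffles sequences irrespective of
    cluster membership.  Deterministic under ``seed``.
    """
    if mode not in (RANDOM, CLUSTER):
        raise ValueError(f"unknown split mode {mode!r}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    if mode == CLUSTER:
        units = clusters.cluster_ids
        if len(units) < 3:
            raise ValueError("cluster mode needs at least 3 clusters")
    else:
        units = sorted(clusters.member_of)
    units = list(units)
    rng.shuffle(units)
    n_train, n_valid, n_test = _largest_remainder_counts(len(units), ratios)
    chunks = (
        units[:n_train],
        units[n_train : n_train + n_valid],
        units[n_train + n_valid :],
    )
    if mode == CLUSTER:
        members = clusters.members_by_cluster()
        sets = [set(s for cid in chunk for s in members[cid]) for chunk in chunks]
    else:
        sets = [set(chunk) for chunk in chunks]
    return DatasetSplit(*sets, mode=mode, ratios=tuple(ratios))


def expand_members(
    split: DatasetSplit,
    clusters: ClusterTable,
    train_mode: str = ALL_MEMBERS,
) -> tuple[list[str], list[str], list[str]]:
    """Resolve redundancy mode into concrete sequence-id lists.

    Validation and test sets always contain only cluster representatives
    (non-redundant sequences); the training set contains either all cluster
    members or representatives only.
    """
    if train_mode not in (ALL_MEMBERS, REPRESENTATIVES_ONLY):
        raise ValueError(f"unknown train_mode {train_mode!r}")
    reps = set(clusters.representative.values())
    for sid in split.train | split.valid | split.test:
        cid = clusters.member_of.get(sid)
        if cid is None:
            raise CorpusFormatError(f"sequence {sid!r} missing from cluster table")
        if cid not in clusters.representative:
            raise CorpusFormatError(f"cluster {cid!r} has no representative")
    if train_mode == ALL_MEMBERS:
        train = sorted(split.train)
    else:
        train = sorted(split.train & reps)
    valid = sorted(split.valid & reps)
    test = sorted(split.test & reps)
    return train, valid, test


def subsample_training(
    split: DatasetSplit,
    clusters: ClusterTable,
    fraction: float,
    seed: int = 0,
) -> DatasetSplit:
    """Keep ``ceil(fraction * K)`` of the K training clusters; valid/test fixed.

    Nested: with the same seed, the clusters kept at a smaller fraction are a
    subset of those kept at a larger one, so learning curves share data.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    train_clusters = sorted({clusters.member_of[s] for s in split.train})
    rng = np.random.default_rng(seed)
    order = list(train_clusters)
    rng.shuffle(order)
    keep = set(order[: math.ceil(fraction * len(order))])
    members = clusters.members_by_cluster()
    train = {s for cid in keep for s in members[cid] if s in split.train}
    return DatasetSplit(
        train=train,
        valid=set(split.valid),
        test=set(split.test),
        mode=split.mode,
        ratios=split.ratios,
    )


# ---------------------------------------------------------------------------
# File I/O: FASTA for sequences, TSV for clusters and labels
# ---------------------------------------------------------------------------


def read_fasta(path, vocab: AminoAcidVocabulary | None = None, permissive=False):
    """Read a FASTA file into ProteinRecords, normalizing case."""
    vocab = vocab or AminoAcidVocabulary()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise CorpusFormatError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise CorpusFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), vocab, permissive=permissive)
        if not seq:
            raise CorpusFormatError(f"{path}: empty sequence for id {rec.id!r}")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def read_cluster_table(path, known_ids: set[str] | None = None) -> ClusterTable:
    """TSV with header (seq_id, cluster_id, is_representative)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seq_id", "cluster_id", "is_representative"}
    if not required.issubset(df.columns):
        raise CorpusFormatError(
            f"{path}: cluster table needs columns {sorted(required)}"
        )
    member_of: dict[str, str] = {}
    representative: dict[str, str] = {}
    for row in df.itertuples(index=False):
        sid, cid = str(row.seq_id), str(row.cluster_id)
        if known_ids is not None and sid not in known_ids:
            raise CorpusFormatError(
                f"{path}: cluster row references unknown sequence id {sid!r}"
            )
        if sid in member_of:
            raise CorpusFormatError(f"{path}: duplicate cluster row for {sid!r}")
        member_of[sid] = cid
        if str(row.is_representative).lower() in ("1", "true", "yes"):
            if cid in representative:
                raise CorpusFormatError(
                    f"{path}: cluster {cid!r} has two representatives"
                )
            representative[cid] = sid
    table = ClusterTable(member_of=member_of, representative=representative)
    for cid in table.cluster_ids:
        if cid not in representative:
            raise CorpusFormatError(f"{path}: cluster {cid!r} has no representative")
    return table


def read_label_table(path) -> dict[str, list[str]]:
    """TSV (seq_id, label[, label...]); multiple label columns allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "seq_id" not in df.columns:
        raise CorpusFormatError(f"{path}: label table needs a seq_id column")
    label_cols = [c for c in df.columns if c != "seq_id"]
    labels: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        sid = str(row.seq_id)
        if sid in labels:
            raise CorpusFormatError(f"{path}: duplicate label row for {sid!r}")
        labels[sid] = [str(getattr(row, c)) for c in label_cols]
    return labels


def read_corpus(
    fasta_path,
    cluster_path=None,
    label_path=None,
    permissive: bool = False,
):
    """Cross-referenced corpus load: records + ClusterTable + labels.

    Unlabeled sequences are permitted (LM-only corpora); cluster rows
    referencing unknown sequence ids are rejected.
    """
    records = read_fasta(fasta_path, permissive=permissive)
    ids = {r.id for r in records}
    clusters = (
        read_cluster_table(cluster_path, known_ids=ids)
        if cluster_path
        else ClusterTable.singletons(sorted(ids))
    )
    labels = read_label_table(label_path) if label_path else {}
    for sid in labels:
        if sid not in ids:
            raise CorpusFormatError(f"label row for unknown sequence id {sid!r}")
    for rec in records:
        if rec.id in labels:
            rec.labels = labels[rec.id]
    return records, clusters, labels


def write_fasta(records, path):
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_cluster_table(clusters: ClusterTable, path):
    reps = set(clusters.representative.values())
    rows = [
        {"seq_id": s, "cluster_id": c, "is_representative": int(s in reps)}
        for s, c in sorted(clusters.member_of.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_label_table(labels: dict[str, list[str]], path):
    rows = []
    for sid in sorted(labels):
        vals = labels[sid]
        if not isinstance(vals, (list, tuple)):
            vals = [vals]
        rows.append({"seq_id": sid, **{f"label_{i}": v for i, v in enumerate(vals)}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
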