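"""One-hot + PSSM encoding and the convolutional baseline classifier.

The baseline follows the classical recipe for sequence classification with
evolutionary features: each sequence is one-hot encoded over the 26-symbol
residue vocabulary and concatenated with an L×20 position-specific scoring
matrix (log-odds over the 20 standard amino acids), zero-padded to a fixed
1024×46 input.  PSSMs come either from an internal alignment-based provider
(tests, small corpora) or from a PSI-BLAST adapter run with 3 iterations at
e-value 0.001 against a database whose composition controls test-set leakage:
``clean`` databases contain training-cluster members only, ``leaky`` ones the
full corpus.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import DatasetSplit, ClusterTable, write_fasta
from .nn import (
    AdaMax,
    Conv1d,
    Linear,
    Module,
    Tensor,
    cross_entropy_logits,
    dropout_mask,
    maxpool1d,
    no_grad,
)
from .vocab import STANDARD_RESIDUES, AminoAcidVocabulary, ProteinRecord

MAX_LEN = 1024
N_ONEHOT = 26
N_PSSM = 20
INPUT_WIDTH = N_ONEHOT + N_PSSM

CLEAN = "clean"
LEAKY = "leaky"

# residue column order used by PSI-BLAST ASCII PSSM output
PSIBLAST_RESIDUE_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")


@dataclass
class PSSMatrix:
    """L×20 log-odds profile over the standard amino acids."""

    scores: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_PSSM:
            raise ValueError(
                f"PSSM must have 20 columns, got shape {self.scores.shape}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


def one_hot(record: ProteinRecord, vocab: AminoAcidVocabulary | None = None):
    """L×26 one-hot encoding in the fixed vocabulary residue order."""
    vocab = vocab or AminoAcidVocabulary()
    L = len(record.sequence)
    out = np.zeros((L, N_ONEHOT))
    for i, ch in enumerate(record.sequence):
        out[i, vocab.residue_index(ch)] = 1.0
    return out


def pssm_from_alignment(
    aligned_sequences, background=None, pseudocount: float = 1.0
) -> PSSMatrix:
    """Log-odds PSSM from equal-length aligned sequences.

    score(i, a) = log( (count(i, a) + pseudocount/20) / (N + pseudocount)
                       / background(a) )

    The internal profile provider used when no database search is wanted.
    """
    seqs = list(aligned_sequences)
    if not seqs:
        raise ValueError("empty alignment")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    if background is None:
        background = np.full(N_PSSM, 1 / N_PSSM)
    background = np.asarray(background, dtype=float)
    counts = np.zeros((L, N_PSSM))
    for s in seqs:
        for i, ch in enumerate(s):
            if ch in STANDARD_RESIDUES:
                counts[i, STANDARD_RESIDUES.index(ch)] += 1
    freq = (counts + pseudocount / N_PSSM) / (len(seqs) + pseudocount)
    return PSSMatrix(np.log(freq / background), provenance={"source": "alignment"})


def _ungapped_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def profile_search_pssm(
    record: ProteinRecord,
    database,
    iterations: int = 3,
    score_threshold: float = 0.0,
    max_hits: int = 50,
    pseudocount: float = 1.0,
) -> PSSMatrix:
    """Internal iterative profile search (query-anchored, ungapped).

    Emulates position-specific iterative database search for corpora without
    indels: the query's single-sequence profile seeds the search; in each
    iteration every same-length database sequence is scored by its summed
    per-position log-odds under the current profile, sequences with a
    positive mean score (above ``score_threshold`` per residue) become hits,
    and the profile is rebuilt from the query plus its hits.  Three
    iterations let the profile walk out from near-identical cluster members
    to remote same-family homologs, exactly the mechanism that makes
    position-specific search more sensitive than pairwise identity.  For real
    (gapped) data use the PSI-BLAST adapter instead.
    """
    L = len(record.sequence)
    candidates = [
        s for s in database if len(s.sequence) == L and s.id != record.id
    ]
    cand_idx = [
        [STANDARD_RESIDUES.index(c) if c in STANDARD_RESIDUES else -1
         for c in s.sequence]
        for s in candidates
    ]
    hits: list[int] = []
    aligned = [record.sequence]
    pssm = pssm_from_alignment(aligned, pseudocount=pseudocount)
    for _ in range(iterations):
        scores = []
        for ci, idx in enumerate(cand_idx):
            s = sum(pssm.scores[i, a] for i, a in enumerate(idx) if a >= 0)
            scores.append((s / L, ci))
        new_hits = [ci for s, ci in sorted(scores, reverse=True)[:max_hits]
                    if s > score_threshold]
        if set(new_hits) == set(hits):
            break
        hits = new_hits
        aligned = [record.sequence] + [candidates[ci].sequence for ci in hits]
        pssm = pssm_from_alignment(aligned, pseudocount=pseudocount)
    pssm.provenance.update({"source": "profile_search", "n_hits": len(hits),
                            "iterations": iterations})
    return pssm


class ExternalToolError(RuntimeError):
    pass


def parse_ascii_pssm(text: str) -> PSSMatrix:
    """Parse PSI-BLAST ``-out_ascii_pssm`` output.

    The dialect: a header line listing the 20 residues twice (log-odds block
    then percentage block), then one row per position starting with the
    position index and residue, followed by 20 integer log-odds scores.
    Columns are remapped from PSI-BLAST residue order to our alphabetical
    vocabulary order.
    """
    rows = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
            rows.append([float(x) for x in parts[2:22]])
    if not rows:
        raise ExternalToolError("no PSSM rows found in ASCII output")
    raw = np.array(rows)
    remap = [PSIBLAST_RESIDUE_ORDER.index(aa) for aa in STANDARD_RESIDUES]
    return PSSMatrix(raw[:, remap], provenance={"source": "psiblast"})


def build_pssm_database(
    records,
    split: DatasetSplit,
    clusters: ClusterTable,
    mode: str,
    out_dir,
) -> Path:
    """Write the search database FASTA for the requested leakage mode.

    ``clean`` keeps only members of training clusters; ``leaky`` keeps the
    full corpus.  If ``makeblastdb`` is available the FASTA is indexed.
    """
    if mode not in (CLEAN, LEAKY):
        raise ValueError(f"unknown PSSM database mode {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if mode == CLEAN:
        train_clusters = {clusters.member_of[s] for s in split.train}
        keep = [r for r in records if clusters.member_of[r.id] in train_clusters]
    else:
        keep = list(records)
    fasta = out_dir / f"pssm_db_{mode}.fasta"
    write_fasta(keep, fasta)
    exe = shutil.which("makeblastdb")
    if exe is not None:
        subprocess.run(
            [exe, "-in", str(fasta), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
    return fasta


def psiblast_command(query_fasta, database, out_pssm) -> list[str]:
    """The PSI-BLAST invocation: 3 iterations, e-value threshold 0.001."""
    return [
        "psiblast",
        "-query", str(query_fasta),
        "-db", str(database),
        "-num_iterations", "3",
        "-evalue", "0.001",
        "-out_ascii_pssm", str(out_pssm),
        "-save_pssm_after_last_round",
    ]


def psiblast_pssm(record: ProteinRecord, database_path, mode: str = CLEAN) -> PSSMatrix:
    """Run PSI-BLAST for one query and parse its ASCII PSSM.

    Falls back to a zero matrix (with a warning) when the search yields no
    hits, so pipelines keep running on sparse databases.
    """
    if shutil.which("psiblast") is None:
        raise ExternalToolError(
            "psiblast executable not found on PATH; install BLAST+ or use "
            "pssm_from_alignment"
        )
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        out_pssm = Path(tmp) / "query.pssm"
        write_fasta([record], query)
        cmd = psiblast_command(query, database_path, out_pssm)
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(
                f"psiblast failed (exit {proc.returncode}): {proc.stderr[:500]}"
            )
        if not out_pssm.exists():
            warnings.warn(
                f"psiblast produced no PSSM for {record.id!r} (no hits); "
                "falling back to a zero matrix"
            )
            return PSSMatrix(
                np.zeros((len(record.sequence), N_PSSM)),
                provenance={"source": "psiblast", "mode": mode, "no_hits": True},
            )
        pssm = parse_ascii_pssm(out_pssm.read_text())
        pssm.provenance["mode"] = mode
        return pssm


def encode_input(
    record: ProteinRecord,
    pssm: PSSMatrix | None = None,
    vocab: AminoAcidVocabulary | None = None,
    max_len: int = MAX_LEN,
) -> np.ndarray:
    """1024×46 baseline input: one-hot block ‖ PSSM block, zero-padded.

    ``pssm=None`` is the sequence-only mode (zero PSSM block).  Sequences
    longer than ``max_len`` keep their N-terminal ``max_len`` residues.
    """
    L = len(record.sequence)
    if pssm is not None and len(pssm) != L:
        raise ValueError(
            f"PSSM rows ({len(pssm)}) do not match sequence length ({L})"
        )
    out = np.zeros((max_len, INPUT_WIDTH))
    Lk = min(L, max_len)
    oh = one_hot(record, vocab)
    out[:Lk, :N_ONEHOT] = oh[:Lk]
    if pssm is not None:
        out[:Lk, N_ONEHOT:] = pssm.scores[:Lk]
    return out


# ---------------------------------------------------------------------------
# CNN baseline
# ---------------------------------------------------------------------------


@dataclass
class CNNSpec:
    """Seven valid-padding conv layers (kernel 3, ReLU, maxpool 2) and three
    dense layers with 25% dropout, softmax output sized to the task.

    ``width_scale`` shrinks every layer width for CPU-sized test profiles
    while preserving the layer structure.
    """

    conv_filters: tuple[int, ...] = (1024, 512, 512, 512, 256, 256, 256)
    kernel: int = 3
    dense_units: tuple[int, ...] = (512, 256, 128)
    dropout: float = 0.25
    n_outputs: int = 6
    width_scale: float = 1.0
    input_len: int = MAX_LEN
    lr: float = 5e-3
    batch_size: int = 16
    seed: int = 0

    def scaled_conv(self) -> list[int]:
        return [max(1, int(round(f * self.width_scale))) for f in self.conv_filters]

    def scaled_dense(self) -> list[int]:
        return [max(1, int(round(u * self.width_scale))) for u in self.dense_units]


class BaselineCNN(Module):
    def __init__(self, spec: CNNSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.convs = []
        c_in, length = INPUT_WIDTH, spec.input_len
        for f in spec.scaled_conv():
            self.convs.append(Conv1d(c_in, f, spec.kernel, rng))
            length = (length - spec.kernel + 1) // 2
            c_in = f
        if length < 1:
            raise ValueError("input too short for the convolutional stack")
        self.denses = []
        n_in = length * c_in
        for u in spec.scaled_dense():
            self.denses.append(Linear(n_in, u, rng, gain=np.sqrt(2.0)))
            n_in = u
        self.out = Linear(n_in, spec.n_outputs, rng)
        self.flat_len = length * c_in
        self._rng = np.random.default_rng(spec.seed + 1)

    def forward(self, x: np.ndarray, train: bool = False) -> Tensor:
        """x: (B, L, 46) -> logits (B, n_outputs)."""
        h = Tensor(x)
        for conv in self.convs:
            h = maxpool1d(conv(h).relu(), 2)
        B = h.shape[0]
        h = h.reshape(B, self.flat_len)
        for dense in self.denses:
            h = dense(h).relu()
            if train and self.spec.dropout > 0:
                h = h * Tensor(dropout_mask(self._rng, h.shape, self.spec.dropout))
        return self.out(h)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters_all())

    def layer_structure(self) -> dict:
        return {
            "n_conv": len(self.convs),
            "n_dense": len(self.denses) + 1,  # incl. softmax output layer
            "conv_filters": [c.c_out for c in self.convs],
            "dense_units": [d.weight.shape[1] for d in self.denses],
        }


def train_cnn(
    spec: CNNSpec,
    inputs: np.ndarray,
    labels: np.ndarray,
    epochs: int = 5,
    valid: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Minimize categorical cross-entropy with AdaMax.

    ``inputs``: (N, L, 46) encoded matrices; returns (model, history).
    """
    model = BaselineCNN(spec)
    opt = AdaMax(model.parameters(), lr=spec.lr)
    rng = np.random.default_rng(spec.seed + 2)
    labels = np.asarray(labels)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(inputs))
        losses = []
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            logits = model.forward(inputs[idx], train=True)
            loss = cross_entropy_logits(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite CNN loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if valid is not None:
            xv, yv = valid
            entry["valid_accuracy"] = float(
                (predict_cnn(model, xv).argmax(axis=1) == yv).mean()
            )
        history.append(entry)
    return model, history


def predict_cnn(model: BaselineCNN, inputs: np.ndarray, batch_size: int = 32):
    probs = []
    with no_grad():
        for start in range(0, len(inputs), batch_size):
            logits = model.forward(inputs[start : start + batch_size], train=False)
            probs.append(logits.softmax(axis=-1).data)
    return np.concatenate(probs, axis=0)
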