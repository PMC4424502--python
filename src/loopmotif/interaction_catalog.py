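"""Interaction-pair catalogs and Match-style PWM promoter scanning.

Pair catalogs (miR->gene, miR->TF, TF->gene) arrive as plain TSV files with
columns ``source_id, target_id, catalog`` and are merged with *union*
semantics: the same (source, target) pair contributed by several databases
collapses to one pair whose provenance is the set of catalog names.  Pairs
are then restricted to endpoints that are differentially expressed at a
given time point, picking up a typed edge class from the endpoint classes.

De-novo TF->gene prediction scans promoter sequences with position weight
matrices using the Match matrix-similarity score: each PWM position i with
base frequencies f(i,b) carries an information weight
I(i) = sum_b f(i,b) * ln(4 f(i,b)), and a window s scores

    score(s) = (sum_i I(i) f(i, s_i) - Min) / (Max - Min)

where Max/Min substitute the per-position max/min frequency.  Scores lie in
[0, 1]; 1 is the consensus, 0 the anti-consensus.  Both strands are scanned
and a TF->gene pair is emitted when the best window reaches the threshold
(0.8 by default, a stringent cutoff intended to limit false positives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "load_pairs",
    "load_and_merge_pairs",
    "merge_pairs",
    "restrict_to_de",
    "PWM",
    "load_transfac_pwms",
    "match_scan",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_FREQ_FLOOR = 1e-4

EDGE_MIR_TF = "miR->TF"
EDGE_MIR_GENE = "miR->gene"
EDGE_TF_GENE = "TF->gene"


# ---------------------------------------------------------------------------
# pair catalogs


def load_pairs(path) -> pd.DataFrame:
    """Read one pair-catalog TSV (source_id, target_id, catalog).

    A header row matching the column names is permitted; malformed rows are
    rejected with their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:2] == ["source_id", "target_id"]:
                continue
            if len(fields) < 3 or any(not f.strip() for f in fields[:3]):
                raise ValueError(f"{path}: malformed pair row at line {lineno}: {line!r}")
            rows.append((fields[0], fields[1], fields[2]))
    df = pd.DataFrame(rows, columns=["source_id", "target_id", "catalog"])
    df["provenance"] = [frozenset([c]) for c in df["catalog"]]
    return df.drop(columns="catalog")


def merge_pairs(*pair_frames: pd.DataFrame) -> pd.DataFrame:
    """Union of pair sets; duplicate (source, target) collapse with provenance union."""
    if not pair_frames:
        return pd.DataFrame(columns=["source_id", "target_id", "provenance"])
    cat = pd.concat(pair_frames, ignore_index=True)
    if (cat["source_id"] == cat["target_id"]).any():
        bad = cat.loc[cat["source_id"] == cat["target_id"], "source_id"].iloc[0]
        raise ValueError(f"self-pair not allowed: {bad}")
    merged = (
        cat.groupby(["source_id", "target_id"], sort=True)["provenance"]
        .agg(lambda sets: frozenset().union(*sets))
        .reset_index()
    )
    return merged


def load_and_merge_pairs(paths) -> pd.DataFrame:
    """Load several catalog files and merge them with union semantics."""
    return merge_pairs(*[load_pairs(p) for p in paths])


def restrict_to_de(
    pairs: pd.DataFrame, de_results: pd.DataFrame, time_h: float
) -> pd.DataFrame:
    """Keep pairs whose endpoints both pass DE at ``time_h``; type the edges.

    ``de_results`` must carry class labels (miR / TF / mRNA, from
    :func:`loopmotif.expression_processing.classify_entities`).  Edge classes:
    miR source with TF target -> miR->TF, miR source with mRNA target ->
    miR->gene, TF source -> TF->gene.  A passing source classed mRNA cannot
    regulate and is rejected as a catalog error.
    """
    valid = {"miR", "TF", "mRNA"}
    seen = set(de_results["class"].unique())
    if not seen <= valid:
        raise ValueError(f"de_results carry unclassified labels: {sorted(seen - valid)}")
    at_t = de_results[(de_results["time_h"] == float(time_h)) & de_results["passes"]]
    cls = dict(zip(at_t["entity_id"], at_t["class"]))

    rows = []
    for rec in pairs.itertuples(index=False):
        src_c = cls.get(rec.source_id)
        tgt_c = cls.get(rec.target_id)
        if src_c is None or tgt_c is None:
            continue
        if src_c == "miR":
            edge = EDGE_MIR_TF if tgt_c == "TF" else EDGE_MIR_GENE
        elif src_c == "TF":
            edge = EDGE_TF_GENE
        else:
            raise ValueError(
                f"pair source {rec.source_id!r} is classed mRNA and cannot be a regulator"
            )
        rows.append((rec.source_id, rec.target_id, edge, rec.provenance))
    return pd.DataFrame(rows, columns=["source_id", "target_id", "edge_class", "provenance"])


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass(frozen=True)
class PWM:
    """Position weight matrix of base frequencies over A, C, G, T."""

    id: str
    frequencies: np.ndarray  # shape (length, 4), rows sum to 1

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] < 1:
            raise ValueError(f"PWM {self.id}: frequency matrix must be (length, 4)")
        if np.any(freq < 0) or not np.allclose(freq.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id}: each position's frequencies must sum to 1")
        object.__setattr__(self, "frequencies", freq)

    def __len__(self) -> int:
        return self.frequencies.shape[0]

    @property
    def information(self) -> np.ndarray:
        """Per-position weight I(i) = sum_b f ln(4 f), frequencies floored at 1e-4."""
        f = self.frequencies
        return (f * np.log(4.0 * np.clip(f, _FREQ_FLOOR, None))).sum(axis=1)

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError(f"PWM {id}: a position has zero total count")
        return cls(id=id, frequencies=counts / totals)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.frequencies.argmax(axis=1))


def load_transfac_pwms(path) -> list[PWM]:
    """Parse TRANSFAC-style count blocks into frequency PWMs."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "transfac")
    pwms = []
    for m in records:
        name = m.get("ID") or m.get("AC") or m.name or f"PWM{len(pwms) + 1}"
        counts = np.column_stack([m.counts[b] for b in _BASES])
        pwms.append(PWM.from_counts(name, counts))
    return pwms


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(c, -1) for c in seq.upper()), dtype=np.int64)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _window_scores(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Match similarity score of every window of an encoded sequence."""
    m = len(pwm)
    n = encoded.size
    if n < m:
        return np.empty(0)
    info = pwm.information
    freq = pwm.frequencies
    weighted = freq * info[:, None]  # I(i) * f(i, b)
    w_min = weighted.min(axis=1)
    lo = w_min.sum()
    hi = weighted.max(axis=1).sum()
    # N (code -1) contributes the position minimum: conservative on masked bases
    per_base = np.column_stack([weighted, w_min])  # column 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(encoded, m)
    raw = per_base[np.arange(m)[None, :], windows].sum(axis=1)
    if hi == lo:  # flat matrix carries no information; nothing can match
        return np.zeros(n - m + 1)
    return (raw - lo) / (hi - lo)


def scan_sequence(pwm: PWM, seq: str) -> tuple[float, str, int] | None:
    """Best Match score of ``pwm`` on either strand of ``seq``.

    Returns (best_score, strand, offset) with the offset 0-based on the
    forward strand, or None when the sequence is shorter than the matrix.
    """
    if len(seq) < len(pwm):
        warnings.warn(f"PWM {pwm.id} is longer than the sequence; no windows scanned")
        return None
    fwd = _window_scores(pwm, _encode(seq))
    rev = _window_scores(pwm, _encode(seq.translate(_COMPLEMENT)[::-1]))
    i_f, i_r = int(fwd.argmax()), int(rev.argmax())
    if rev[i_r] > fwd[i_f]:
        # map the reverse-strand window start back to forward coordinates
        return float(rev[i_r]), "-", len(seq) - len(pwm) - i_r
    return float(fwd[i_f]), "+", i_f


def match_scan(promoters, pwms, threshold: float = 0.8) -> pd.DataFrame:
    """Scan promoter FASTA with PWMs; emit TF->gene pairs with best score >= threshold.

    Parameters
    ----------
    promoters
        Path to a FASTA file (record id = gene id) or an iterable of
        ``(gene_id, sequence)`` tuples.
    pwms
        Iterable of :class:`PWM` (PWM id = TF id).
    threshold
        Matrix-similarity cutoff in [0, 1].
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if isinstance(promoters, (str, bytes)) or hasattr(promoters, "read"):
        seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(promoters, "fasta")]
    else:
        seqs = [(gid, str(s)) for gid, s in promoters]
    rows = []
    for pwm in pwms:
        for gene_id, seq in seqs:
            hit = scan_sequence(pwm, seq)
            if hit is not None and hit[0] >= threshold:
                rows.append((pwm.id, gene_id, hit[0], hit[1], hit[2]))
    return pd.DataFrame(
        rows, columns=["tf_id", "gene_id", "best_score", "strand", "offset"]
    )
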