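"""PPI-network graph embedding: biased random walks + skip-gram.

The protein–protein interaction network is binarized from a STRING-style
scored edge list (combined scores 0–1000; default high-confidence cutoff
700).  Local network structure is then captured by second-order biased
random walks: from current node ``v``, reached from previous node ``t``,
the unnormalized weight of stepping to neighbor ``x`` is

    1/p  if x == t                (distance d(t,x) = 0, a return)
    1    if x is adjacent to t    (d(t,x) = 1)
    1/q  otherwise                (d(t,x) = 2)

so the return parameter ``p`` and in–out parameter ``q`` interpolate
between breadth-first and depth-first exploration.  The walk corpus is fed
to a skip-gram model with negative sampling, trained here with plain numpy
mini-batch SGD, which yields one k-dimensional vector per protein; a
variant inherits the vector of the protein its gene maps to (zero vector
when the gene is absent from the network, so feature rows stay aligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import (ContractError, DeadEndError, EmptyGraphError,
                         FormatError, ParameterError)
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 700


# ---------------------------------------------------------------------------
# graph construction


def read_edge_list(path) -> list[tuple[str, str, int]]:
    """Read a STRING detailed-links style TSV: protein1 protein2 combined_score."""
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    need = ["protein1", "protein2", "combined_score"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"edge list lacks column(s): {missing}")
    return [(str(a), str(b), int(s)) for a, b, s in
            zip(df.protein1, df.protein2, df.combined_score)]


def build_adjacency(edges, score_threshold: int = DEFAULT_SCORE_THRESHOLD,
                    roster=None) -> nx.Graph:
    """Binarize a scored edge list into an undirected simple graph.

    An edge exists iff its best combined score reaches ``score_threshold``;
    self-edges are dropped and duplicate (a,b)/(b,a) pairs merged keeping
    the maximum score.  Nodes with no surviving edge are retained only when
    listed in ``roster``.
    """
    best: dict[tuple[str, str], int] = {}
    for a, b, s in edges:
        s = int(s)
        if not 0 <= s <= 1000:
            raise FormatError(f"combined_score outside 0..1000: ({a},{b},{s})")
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if s > best.get(key, -1):
            best[key] = s
    g = nx.Graph()
    if roster is not None:
        g.add_nodes_from(str(n) for n in roster)
    for (a, b), s in best.items():
        if s >= score_threshold:
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise EmptyGraphError(
            f"no edge reaches combined_score >= {score_threshold}")
    return g


# ---------------------------------------------------------------------------
# biased second-order random walks


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the biased walk and corpus generation."""

    p: float = 1.0            # return parameter: 1/p weight on revisiting t
    q: float = 1.0            # in-out parameter: 1/q weight on leaving t's neighborhood
    walk_length: int = 80     # nodes per walk, start node included
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ParameterError(f"p and q must be positive, got p={self.p}, q={self.q}")
        if int(self.walk_length) != self.walk_length or self.walk_length < 2:
            raise ParameterError(f"walk_length must be an integer >= 2, got {self.walk_length}")
        if int(self.walks_per_node) != self.walks_per_node or self.walks_per_node < 1:
            raise ParameterError(f"walks_per_node must be an integer >= 1, got {self.walks_per_node}")


def transition_weight(t, v, x, cfg: WalkConfig, g: nx.Graph) -> float:
    """Unnormalized second-order weight of the step v -> x given previous t.

    With no previous node (first step of a walk, ``t is None``) every
    neighbor has weight 1.
    """
    if not g.has_edge(v, x):
        raise ContractError(f"{x!r} is not adjacent to {v!r}")
    if t is None:
        return 1.0
    if x == t:
        return 1.0 / cfg.p
    if g.has_edge(t, x):
        return 1.0
    return 1.0 / cfg.q


def step_distribution(t, v, cfg: WalkConfig, g: nx.Graph):
    """Normalized next-step distribution over v's neighbors.

    Returns ``(neighbors, probs)`` with neighbors in sorted order so the
    distribution is deterministic for a given graph.
    """
    nbrs = sorted(g.neighbors(v))
    if not nbrs:
        raise DeadEndError(f"node {v!r} has no neighbors")
    w = np.array([transition_weight(t, v, x, cfg, g) for x in nbrs], dtype=float)
    return nbrs, w / w.sum()


def sample_step(t, v, cfg: WalkConfig, g: nx.Graph, rng: np.random.Generator):
    """Draw one next node by inverse-CDF sampling of the unnormalized weights."""
    nbrs = sorted(g.neighbors(v))
    if not nbrs:
        raise DeadEndError(f"node {v!r} has no neighbors")
    w = np.array([transition_weight(t, v, x, cfg, g) for x in nbrs], dtype=float)
    cum = np.cumsum(w)
    u = rng.random() * cum[-1]
    return nbrs[int(np.searchsorted(cum, u, side="right"))]


def sample_steps(t, v, cfg: WalkConfig, g: nx.Graph,
                 rng: np.random.Generator, n: int) -> list:
    """Draw ``n`` i.i.d. next nodes from state (t, v), vectorized.

    Same inverse-CDF sampling on the unnormalized weights as
    :func:`sample_step`; useful for Monte-Carlo checks of the step
    distribution.
    """
    nbrs = sorted(g.neighbors(v))
    if not nbrs:
        raise DeadEndError(f"node {v!r} has no neighbors")
    w = np.array([transition_weight(t, v, x, cfg, g) for x in nbrs], dtype=float)
    cum = np.cumsum(w)
    idx = np.searchsorted(cum, rng.random(n) * cum[-1], side="right")
    return [nbrs[i] for i in idx]


def simulate_walk(start, cfg: WalkConfig, g: nx.Graph,
                  rng: np.random.Generator) -> list:
    """One biased walk of up to ``walk_length`` nodes starting at ``start``.

    Truncates early only at a dead end (an isolated start yields a
    length-1 walk).
    """
    if start not in g:
        raise ContractError(f"start node {start!r} not in graph")
    walk = [start]
    prev = None
    while len(walk) < cfg.walk_length:
        cur = walk[-1]
        if g.degree(cur) == 0:
            break
        nxt = sample_step(prev, cur, cfg, g, rng)
        walk.append(nxt)
        prev = cur
    return walk


def generate_corpus(g: nx.Graph, cfg: WalkConfig) -> list[list]:
    """``walks_per_node`` walks from every node, reproducibly.

    Each (start node, repeat) pair gets its own RNG derived from
    ``(cfg.seed, node rank, repeat)``, so the corpus is byte-identical for
    a given seed regardless of how the loop might be scheduled.
    """
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("cannot walk an empty graph")
    corpus = []
    for node_rank, node in enumerate(sorted(g.nodes)):
        for r in range(cfg.walks_per_node):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed,
                                       spawn_key=(node_rank, r)))
            corpus.append(simulate_walk(node, cfg, g, rng))
    return corpus


def write_corpus(corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for walk in corpus:
            fh.write(" ".join(str(n) for n in walk) + "\n")


def read_corpus(path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.split() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


@dataclass
class EmbeddingMatrix:
    """Per-protein embedding vectors: row ``node_index[n]`` of ``U`` is node n."""

    node_index: dict
    U: np.ndarray
    epoch_loss: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.U.shape[1]

    def vector(self, node) -> np.ndarray:
        i = self.node_index.get(node)
        if i is None:
            return np.zeros(self.k)
        return self.U[i]


def _skipgram_pairs(corpus, vocab_index, window: int) -> np.ndarray:
    """All (center, context) index pairs within a fixed window."""
    chunks = []
    for walk in corpus:
        ids = np.array([vocab_index[n] for n in walk], dtype=np.int64)
        for off in range(1, window + 1):
            if len(ids) <= off:
                break
            chunks.append(np.stack([ids[:-off], ids[off:]], axis=1))
            chunks.append(np.stack([ids[off:], ids[:-off]], axis=1))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(chunks, axis=0)


def _scatter_mean(W, rows, grads, lr):
    """SGD step ``W[r] -= lr * mean(grads at r)`` for each touched row."""
    from scipy import sparse

    b = len(rows)
    nv = W.shape[0]
    onehot = sparse.csr_matrix(
        (np.ones(b), (rows, np.arange(b))), shape=(nv, b))
    sums = onehot @ grads
    counts = np.bincount(rows, minlength=nv)
    touched = counts > 0
    W[touched] -= lr * sums[touched] / counts[touched, None]


def train_skipgram(corpus, k: int = 64, window: int = 5, epochs: int = 5,
                   negative_samples: int = 5, seed: int = 0,
                   nodes=None, learning_rate: float = 0.5,
                   batch_size: int = 8192) -> EmbeddingMatrix:
    """Fit skip-gram embeddings with negative sampling on a walk corpus.

    Standard word2vec-style objective: for each (center, context) pair
    within ``window`` positions of a walk, maximize
    log sigma(u_c . u'_o) + sum_neg log sigma(-u_c . u'_neg), negatives
    drawn from the unigram distribution raised to 3/4.  Optimized by
    mini-batch SGD with a linearly decaying learning rate; single-threaded
    and fully deterministic for a given seed.

    ``nodes``, when given, fixes the output row set: nodes absent from the
    corpus receive the zero vector.
    """
    if k < 2 or int(k) != k:
        raise ParameterError(f"embedding dimension k must be an integer >= 2, got {k}")
    corpus = [w for w in corpus if w]
    if not corpus:
        raise ContractError("corpus is empty")

    counts: dict = {}
    for walk in corpus:
        for n in walk:
            counts[n] = counts.get(n, 0) + 1
    vocab = sorted(counts)
    vocab_index = {n: i for i, n in enumerate(vocab)}
    nv = len(vocab)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    W_in = (rng.random((nv, k)) - 0.5) / k
    W_out = np.zeros((nv, k))

    noise = np.array([counts[n] for n in vocab], dtype=float) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    pairs = _skipgram_pairs(corpus, vocab_index, window)
    n_pairs = len(pairs)
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    min_lr = 1e-4
    losses = []
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        epoch_loss = 0.0
        for lo in range(0, n_pairs, batch_size):
            idx = order[lo:lo + batch_size]
            centers, contexts = pairs[idx, 0], pairs[idx, 1]
            b = len(centers)
            negs = np.searchsorted(noise_cdf, rng.random((b, negative_samples)))

            lr = max(min_lr, learning_rate * (1 - batch_no / total_batches))
            batch_no += 1

            vc = W_in[centers]                      # (b, k)
            vo = W_out[contexts]                    # (b, k)
            vn = W_out[negs]                        # (b, neg, k)

            pos_logit = np.einsum("ij,ij->i", vc, vo)
            neg_logit = np.einsum("ij,inj->in", vc, vn)
            pos_sig = expit(pos_logit)
            neg_sig = expit(neg_logit)

            epoch_loss += float(
                -np.log(np.clip(pos_sig, 1e-10, None)).sum()
                - np.log(np.clip(1 - neg_sig, 1e-10, None)).sum()
            )

            g_pos = (pos_sig - 1.0)[:, None]        # d loss / d pos_logit
            g_neg = neg_sig[:, :, None]             # d loss / d neg_logit

            grad_c = g_pos * vo + np.einsum("inj,in->ij", vn, neg_sig)
            # rows repeat many times within a batch on small vocabularies;
            # average (not sum) per-row gradients so the step size stays O(lr)
            _scatter_mean(W_in, centers, grad_c, lr)
            out_rows = np.concatenate([contexts, negs.ravel()])
            out_grads = np.concatenate(
                [g_pos * vc, (g_neg * vc[:, None, :]).reshape(-1, k)])
            _scatter_mean(W_out, out_rows, out_grads, lr)
        losses.append(epoch_loss / n_pairs)

    if nodes is not None:
        all_nodes = sorted(str(n) for n in nodes)
        U = np.zeros((len(all_nodes), k))
        index = {}
        n_absent = 0
        for i, n in enumerate(all_nodes):
            index[n] = i
            j = vocab_index.get(n)
            if j is not None:
                U[i] = W_in[j]
            else:
                n_absent += 1
        if n_absent:
            logger.warning("%d node(s) absent from corpus embedded as zero vectors",
                           n_absent)
        return EmbeddingMatrix(index, U, losses)
    return EmbeddingMatrix(vocab_index, W_in, losses)


# ---------------------------------------------------------------------------
# gene mapping and variant-level lookup


def read_gene_map(path) -> dict[str, str]:
    """Read a two-column TSV gene_symbol -> protein_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["gene_symbol", "protein_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"gene map lacks column(s): {missing}")
    return dict(zip(df.gene_symbol, df.protein_id))


def variant_embedding(record: VariantRecord, emb: EmbeddingMatrix,
                      gene_map: dict[str, str]) -> np.ndarray:
    """Embedding vector for a variant = vector of its gene's protein.

    Unmapped genes or proteins absent from the embedding fall back to the
    zero vector (logged), keeping feature rows aligned with the variant set.
    """
    protein = gene_map.get(record.gene)
    if protein is None:
        logger.warning("gene %s has no protein mapping; zero embedding", record.gene)
        return np.zeros(emb.k)
    if protein not in emb.node_index:
        logger.warning("protein %s absent from embedding; zero vector", protein)
        return np.zeros(emb.k)
    return emb.vector(protein)


def write_embedding(emb: EmbeddingMatrix, path) -> None:
    k = emb.k
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\t" + "\t".join(f"v{j + 1}" for j in range(k)) + "\n")
        for node in sorted(emb.node_index):
            row = emb.U[emb.node_index[node]]
            fh.write(node + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def read_embedding(path) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    if "node_id" not in df.columns:
        raise FormatError("embedding table lacks node_id column")
    nodes = df["node_id"].tolist()
    U = df.drop(columns=["node_id"]).to_numpy(dtype=float)
    return EmbeddingMatrix({n: i for i, n in enumerate(nodes)}, U)
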