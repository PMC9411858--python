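"""Repertoire-scale structural clustering and sequence-embedding concordance.

Predicted structures live in a common reference frame, so structural
similarity between two domains V and W is measured without superposition by
counting CA atoms matched one-to-one within 1 Angstrom:

    distance(V, W) = 1 - matched / min(|V|, |W|)

The resulting matrix is clustered with k-medoids (PAM). Sequences are
independently embedded as 126 x 21 = 2,646-dimensional canonical one-hot
vectors, projected to 2-D with t-SNE, and the agreement between structural
clusters and sequence families is scored with the adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from . import regions as regions_mod
from .geometry import kabsch_superpose
from .structure_io import BackboneStructure

logger = logging.getLogger(__name__)

CA_MATCH_CUTOFF = 1.0  # Angstrom
EMBEDDING_ALPHABET = regions_mod.GAP + "ACDEFGHIKLMNPQRSTVWY"  # 21 symbols
EMBEDDING_DIM = regions_mod.N_CANONICAL_POSITIONS * len(EMBEDDING_ALPHABET)


def structural_distance(v: BackboneStructure, w: BackboneStructure,
                        cutoff: float = CA_MATCH_CUTOFF,
                        superpose: bool = False) -> float:
    """1 - (one-to-one CA matches < cutoff) / min(|V|, |W|), in [0, 1].

    No superposition is performed by default (predictions share a frame);
    ``superpose`` enables a CA Kabsch fit first for structures from other
    sources. Matching is greedy one-to-one, closest pairs first, so the
    count never exceeds min(|V|, |W|).
    """
    if len(v) == 0 or len(w) == 0:
        raise ValueError("structures must be non-empty")
    ca_v, ca_w = v.ca_coords(), w.ca_coords()
    if superpose:
        n = min(len(ca_v), len(ca_w))
        transform, _ = kabsch_superpose(ca_v[:n], ca_w[:n])
        ca_v = transform.apply(ca_v)
    d = cdist(ca_v, ca_w)
    pairs = np.argwhere(d < cutoff)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_v = np.zeros(len(ca_v), dtype=bool)
    used_w = np.zeros(len(ca_w), dtype=bool)
    matched = 0
    for i, j in pairs[order]:
        if not used_v[i] and not used_w[j]:
            used_v[i] = used_w[j] = True
            matched += 1
    return 1.0 - matched / min(len(ca_v), len(ca_w))


@dataclass
class StructuralDistanceMatrix:
    ids: list[str]
    D: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def validate(self) -> None:
        if self.D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("diagonal is not zero")
        if np.any((self.D < 0) | (self.D > 1)):
            raise ValueError("entries outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.ids, columns=self.ids)


def distance_matrix(structures: list[BackboneStructure],
                    ids: list[str] | None = None,
                    cutoff: float = CA_MATCH_CUTOFF,
                    superpose: bool = False) -> StructuralDistanceMatrix:
    """All-pairs structural distances; each pair computed once, symmetry by construction."""
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    if ids is None:
        ids = [s.source_id or f"s{i}" for i, s in enumerate(structures)]
    n = len(structures)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = structural_distance(structures[i], structures[j],
                                                    cutoff=cutoff, superpose=superpose)
    out = StructuralDistanceMatrix(list(ids), d)
    out.validate()
    return out


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    medoids: list[str]
    k: int

    def label_array(self, ids: list[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])


def _pam_once(d: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    n = d.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))

    def assign_to(meds):
        a = meds[np.argmin(d[:, meds], axis=1)]
        a[meds] = meds  # duplicate points can tie at distance 0; keep clusters non-empty
        return a

    for _ in range(max_iter):
        assign = assign_to(medoids)
        new_medoids = []
        for m in medoids:
            members = np.where(assign == m)[0]
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(members[np.argmin(within)])
        new_medoids = np.sort(np.array(new_medoids))
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = assign_to(medoids)
    cost = float(d[np.arange(n), assign].sum())
    return medoids, assign, cost


def k_medoids(matrix: StructuralDistanceMatrix, k: int = 12, seed: int = 0,
              restarts: int = 10) -> ClusterAssignment:
    """PAM-style k-medoids on a precomputed distance matrix; best of ``restarts`` runs.

    Deterministic given the seed: restarts draw from one seeded generator and
    ties resolve to the first (lowest-index) optimum.
    """
    n = len(matrix.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        medoids, assign, cost = _pam_once(matrix.D, k, rng)
        if best is None or cost < best[2] - 1e-12:
            best = (medoids, assign, cost)
    medoids, assign, _ = best
    relabel = {m: i for i, m in enumerate(medoids)}
    labels = {matrix.ids[i]: relabel[assign[i]] for i in range(n)}
    return ClusterAssignment(labels, [matrix.ids[m] for m in medoids], k)


def cluster_cost(matrix: StructuralDistanceMatrix,
                 assignment: ClusterAssignment) -> float:
    """Total distance of every item to its cluster medoid."""
    idx = {rid: i for i, rid in enumerate(matrix.ids)}
    medoid_of = {assignment.labels[m]: idx[m] for m in assignment.medoids}
    return float(sum(matrix.D[idx[rid], medoid_of[lab]]
                     for rid, lab in assignment.labels.items()))


# ---------------------------------------------------------------------------
# sequence embedding and 2-D projection

def embed_sequences(sequences: list[tuple[str, str]], numbering_tables=None,
                    boundaries=regions_mod.DEFAULT_BOUNDARIES
                    ) -> tuple[list[str], np.ndarray, list[str]]:
    """Canonical one-hot embedding (length 2,646) per numberable sequence.

    Returns (kept ids, matrix, skipped ids). Unnumberable sequences are
    skipped with a log message rather than failing the batch.
    """
    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped: list[str] = []
    sym_index = {c: i for i, c in enumerate(EMBEDDING_ALPHABET)}
    for rid, seq in sequences:
        numbering = numbering_tables.get(rid) if numbering_tables else None
        try:
            aln = regions_mod.canonical_align(seq, numbering=numbering,
                                              boundaries=boundaries)
        except (regions_mod.UnnumberableSequenceError, ValueError) as exc:
            logger.warning("embed_sequences: skipping %s (%s)", rid, exc)
            skipped.append(rid)
            continue
        vec = np.zeros(EMBEDDING_DIM)
        for pos, letter in enumerate(aln.positions):
            vec[pos * len(EMBEDDING_ALPHABET) + sym_index[letter]] = 1.0
        kept_ids.append(rid)
        rows.append(vec)
    matrix = np.vstack(rows) if rows else np.zeros((0, EMBEDDING_DIM))
    return kept_ids, matrix, skipped


def project_2d(vectors: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """t-SNE projection to 2-D; deterministic given the seed."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 5:
        raise ValueError("need at least 5 vectors for a 2-D projection")
    perplexity = min(perplexity, (vectors.shape[0] - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(vectors)


def concordance(assignment: ClusterAssignment, families: dict[str, int | str]) -> float:
    """Adjusted Rand index between structural clusters and known family labels."""
    if set(assignment.labels) != set(families):
        raise ValueError("assignment and family labels cover different ids")
    ids = sorted(assignment.labels)
    a = [assignment.labels[i] for i in ids]
    b = [families[i] for i in ids]
    return float(adjusted_rand_score(b, a))


# ---------------------------------------------------------------------------
# delimited-text outputs

def write_distance_matrix(matrix: StructuralDistanceMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_distance_matrix(path: str) -> StructuralDistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    out = StructuralDistanceMatrix([str(c) for c in df.columns], df.to_numpy())
    out.validate()
    return out


def write_clusters(assignment: ClusterAssignment, path: str) -> None:
    rows = [{"id": rid, "cluster": lab} for rid, lab in sorted(assignment.labels.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_projection(ids: list[str], coords: np.ndarray, path: str) -> None:
    pd.DataFrame({"id": ids, "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        path, sep="\t", index=False)


def scatter_plot(ids: list[str], coords: np.ndarray, colors: dict[str, float],
                 path: str, title: str = "") -> None:
    """Optional colored 2-D scatter (cluster id or CDR3 length per point)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = [colors[i] for i in ids]
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=c, cmap="tab20", s=12)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
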