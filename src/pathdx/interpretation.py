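"""Interpretability: attention profiles, pathway clustering, code summaries.

The pooled [CLS] hidden vector of the fine-tuned encoder is the pathway
representation; k-means on those vectors (never on the 2-D layout, which is
cosmetic) groups patients into progression/investigation patterns. The
attention profile of a pathway is the final-layer [CLS] query row averaged
over heads, with special-token positions dropped and the rest renormalised —
how much the classifier's pooled representation attends to each medical code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from pathdx.model import SequenceModel
from pathdx.pathways import N_SPECIAL, Pathway, Vocabulary
from pathdx.training import _pad_batch, encode_pathways


@dataclass
class AttentionProfile:
    """Per-token attention weights from [CLS], summing to 1."""

    pathway_id: str
    tokens: list[str]
    weights: np.ndarray


def extract_cls_embedding(
    model: SequenceModel, sequences: Sequence[np.ndarray], batch_size: int = 64
) -> np.ndarray:
    """Final-layer [CLS] hidden vectors, (n, H)."""
    outs = []
    for start in range(0, len(sequences), batch_size):
        ids = _pad_batch(list(sequences[start : start + batch_size]))
        outs.append(model.forward(ids).cls.data)
    return np.vstack(outs)


def embed_pathways(
    model: SequenceModel, pathways: Sequence[Pathway], vocabulary: Vocabulary
) -> np.ndarray:
    seqs = encode_pathways(pathways, vocabulary, model.config.max_len)
    return extract_cls_embedding(model, seqs)


def extract_attention_profile(
    model: SequenceModel,
    pathway: Pathway,
    vocabulary: Vocabulary,
    layer: int | None = None,
) -> AttentionProfile:
    """Head-averaged final-layer [CLS] attention over the pathway's codes.

    ``layer`` overrides the default (final) layer. Special-token positions
    ([CLS] self-attention, padding) are dropped and the remaining weights
    renormalised to sum to 1.
    """
    if len(pathway.tokens) == 0:
        raise ValueError("cannot extract attention profile of an empty pathway")
    seqs = encode_pathways([pathway], vocabulary, model.config.max_len)
    out = model.forward(seqs[0][None, :])
    att = out.attentions[layer if layer is not None else -1]  # (1, heads, N, N)
    cls_row = att[0, :, 0, :].mean(axis=0)  # head-averaged [CLS] query row
    weights = cls_row[1:]  # drop the [CLS] position itself
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate attention row")
    kept = pathway.tokens[-(model.config.max_len - 1):]
    return AttentionProfile(
        pathway_id=pathway.patient_id,
        tokens=list(kept),
        weights=weights / total,
    )


@dataclass
class ClusterReport:
    k: int
    assignments: np.ndarray
    sizes: dict[int, int]
    fractions: dict[int, float]
    inertia: float
    k_scan: list[dict] = field(default_factory=list)
    coords_2d: np.ndarray | None = None
    code_prevalence: dict[int, list[tuple[str, float]]] = field(default_factory=dict)
    top_attended: dict[int, list[tuple[str, float]]] = field(default_factory=dict)


def cluster_pathways(
    embeddings: np.ndarray,
    k: int = 6,
    seed: int = 0,
    n_init: int = 10,
    scan_range: tuple[int, int] = (2, 10),
) -> ClusterReport:
    """k-means over pathway embeddings with a k-scan to audit the choice of k.

    The scan reports inertia and silhouette for k in ``scan_range`` so the
    default k=6 is an auditable decision rather than a constant.
    """
    X = np.asarray(embeddings, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of embeddings {n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(X)
    sizes = {c: int((assignments == c).sum()) for c in range(k)}
    scan = []
    for kk in range(scan_range[0], min(scan_range[1], n - 1) + 1):
        km_k = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        lab = km_k.fit_predict(X)
        sil = float(silhouette_score(X, lab)) if len(set(lab.tolist())) > 1 else float("nan")
        scan.append({"k": kk, "inertia": float(km_k.inertia_), "silhouette": sil})
    return ClusterReport(
        k=k,
        assignments=assignments,
        sizes=sizes,
        fractions={c: s / n for c, s in sizes.items()},
        inertia=float(km.inertia_),
        k_scan=scan,
    )


def cluster_code_summary(
    report: ClusterReport,
    pathways: Sequence[Pathway],
    profiles: Sequence[AttentionProfile] | None = None,
    top_n: int = 20,
) -> ClusterReport:
    """Per-cluster code prevalence and mean attention mass tables.

    Prevalence of group g in a cluster = fraction of the cluster's pathways
    containing g; attention mass = mean per-pathway total attention on g.
    Both sorted descending; top ``top_n`` kept.
    """
    assignments = report.assignments
    if len(assignments) != len(pathways):
        raise ValueError("assignments and pathways length mismatch")
    for c in sorted(set(assignments.tolist())):
        idx = [i for i, a in enumerate(assignments) if a == c]
        counts: dict[str, int] = {}
        for i in idx:
            for g in set(pathways[i].tokens):
                counts[g] = counts.get(g, 0) + 1
        prevalence = sorted(
            ((g, cnt / len(idx)) for g, cnt in counts.items()),
            key=lambda t: (-t[1], t[0]),
        )
        report.code_prevalence[c] = prevalence[:top_n]
        if profiles is not None:
            mass: dict[str, float] = {}
            for i in idx:
                prof = profiles[i]
                for g, w in zip(prof.tokens, prof.weights):
                    mass[g] = mass.get(g, 0.0) + float(w)
            attended = sorted(
                ((g, m / len(idx)) for g, m in mass.items()),
                key=lambda t: (-t[1], t[0]),
            )
            report.top_attended[c] = attended[:top_n]
    return report


def embed_2d(
    embeddings: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """Seeded t-SNE layout for plotting only (never for clustering)."""
    X = np.asarray(embeddings, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 embeddings for a 2-D layout")
    perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return ts.fit_transform(X)
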