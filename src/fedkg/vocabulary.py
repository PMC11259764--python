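"""Clinical concept vocabulary: hierarchy, hypernym designation, abstraction map.

The vocabulary is a directed acyclic graph of clinical concepts (conditions,
measurements, drugs, procedures, observations) with ``parent`` edges pointing
from general to specific.  A subset of concepts is flagged ``is_hypernym``:
these are the generalized expressions a hospital is allowed to export, e.g.
"abnormal kidney function" standing in for a specific eGFR staging finding.
Candidate hypernyms are ranked by hierarchical specificity and by the cohesion
of their descendant leaves, measured as mean pairwise cosine similarity of
leaf embedding vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

DOMAINS = frozenset({"condition", "measurement", "drug", "procedure", "observation"})


class VocabularyError(ValueError):
    """Structural or reference problem in the concept vocabulary."""


class CycleError(VocabularyError):
    """The hierarchy contains a cycle; the message names one member."""


class DanglingParentError(VocabularyError):
    """A concept references a parent that does not exist."""


class EmbeddingError(VocabularyError):
    """A leaf required for a similarity computation has no embedding."""


@dataclass(frozen=True)
class Concept:
    """One vocabulary entry.

    ``parent_ids`` point at more general concepts; a concept without parents
    is a root.  ``embedding`` is an optional fixed-length real vector used to
    score the cohesion of a hypernym's leaves.
    """

    concept_id: str
    name: str
    domain: str
    parent_ids: frozenset[str] = frozenset()
    is_hypernym: bool = False
    embedding: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise VocabularyError("concept_id must be non-empty")
        if self.domain not in DOMAINS:
            raise VocabularyError(
                f"concept {self.concept_id!r}: unknown domain {self.domain!r}"
            )


class ConceptGraph:
    """Validated concept DAG with root/leaf/ancestor queries.

    Depth is the length of the longest root-to-concept path, so "more
    specific" always means strictly deeper in the hierarchy.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self._concepts:
                raise VocabularyError(f"duplicate concept_id {c.concept_id!r}")
            self._concepts[c.concept_id] = c

        g = nx.DiGraph()
        g.add_nodes_from(self._concepts)
        for c in self._concepts.values():
            for p in c.parent_ids:
                if p not in self._concepts:
                    raise DanglingParentError(
                        f"concept {c.concept_id!r} references missing parent {p!r}"
                    )
                g.add_edge(p, c.concept_id)  # parent -> child
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(f"hierarchy contains a cycle through {cycle[0][0]!r}")
        self._nx = g

        self._depth: dict[str, int] = {}
        for node in nx.topological_sort(g):
            preds = list(g.predecessors(node))
            self._depth[node] = 0 if not preds else 1 + max(self._depth[p] for p in preds)

        for c in self._concepts.values():
            if c.is_hypernym and not self.descendant_leaves(c.concept_id):
                raise VocabularyError(
                    f"hypernym {c.concept_id!r} has no descendant leaf"
                )

    # -- basic queries -------------------------------------------------
    def __len__(self) -> int:
        return len(self._concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __iter__(self):
        return iter(sorted(self._concepts))

    def get(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise VocabularyError(f"unknown concept {concept_id!r}") from None

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(sorted(c for c in self._concepts
                            if not self._concepts[c].parent_ids))

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(c for c in self._concepts if self.is_leaf(c)))

    def is_leaf(self, concept_id: str) -> bool:
        self.get(concept_id)
        return self._nx.out_degree(concept_id) == 0

    def children(self, concept_id: str) -> tuple[str, ...]:
        self.get(concept_id)
        return tuple(sorted(self._nx.successors(concept_id)))

    def parents(self, concept_id: str) -> tuple[str, ...]:
        self.get(concept_id)
        return tuple(sorted(self._nx.predecessors(concept_id)))

    def ancestors(self, concept_id: str, include_self: bool = False) -> frozenset[str]:
        self.get(concept_id)
        anc = set(nx.ancestors(self._nx, concept_id))
        if include_self:
            anc.add(concept_id)
        return frozenset(anc)

    def descendant_leaves(self, concept_id: str) -> tuple[str, ...]:
        """Leaves reachable from ``concept_id`` (the concept itself if a leaf)."""
        self.get(concept_id)
        desc = set(nx.descendants(self._nx, concept_id)) | {concept_id}
        return tuple(sorted(d for d in desc if self._nx.out_degree(d) == 0))

    def depth(self, concept_id: str) -> int:
        self.get(concept_id)
        return self._depth[concept_id]

    @property
    def hypernyms(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, v in self._concepts.items() if v.is_hypernym))


# -- vocabulary table IO ----------------------------------------------

_REQUIRED_COLUMNS = ("concept_id", "name", "domain", "parent_ids", "is_hypernym")


def load_vocabulary(path) -> ConceptGraph:
    """Load a concept table (CSV) into a validated :class:`ConceptGraph`.

    Expected columns: ``concept_id,name,domain,parent_ids,is_hypernym`` with
    ``parent_ids`` pipe-separated and an optional ``embedding`` column of
    ``;``-separated floats.  An empty table yields an empty graph.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VocabularyError(f"vocabulary table missing columns: {missing}")
    concepts = []
    for row in df.itertuples(index=False):
        parents = frozenset(p for p in str(row.parent_ids).split("|") if p)
        emb = None
        if "embedding" in df.columns and getattr(row, "embedding", ""):
            emb = tuple(float(x) for x in str(row.embedding).split(";"))
        concepts.append(
            Concept(
                concept_id=row.concept_id,
                name=row.name,
                domain=row.domain,
                parent_ids=parents,
                is_hypernym=str(row.is_hypernym).strip().lower()
                in {"true", "1", "yes", "y"},
                embedding=emb,
            )
        )
    return ConceptGraph(concepts)


def write_vocabulary(graph: ConceptGraph, path) -> None:
    rows = []
    for cid in graph:
        c = graph.get(cid)
        rows.append(
            {
                "concept_id": c.concept_id,
                "name": c.name,
                "domain": c.domain,
                "parent_ids": "|".join(sorted(c.parent_ids)),
                "is_hypernym": str(c.is_hypernym).lower(),
                "embedding": ";".join(repr(x) for x in c.embedding)
                if c.embedding is not None
                else "",
            }
        )
    pd.DataFrame(rows, columns=[*_REQUIRED_COLUMNS, "embedding"]).to_csv(
        path, index=False
    )


# -- hypernym cohesion and mapping ------------------------------------


def leaf_similarity(graph: ConceptGraph, hypernym: str) -> float:
    """Mean pairwise cosine similarity of a hypernym's descendant leaves.

    Returns 1.0 for a single leaf.  Raises :class:`EmbeddingError` when a
    descendant leaf carries no embedding.
    """
    leaves = graph.descendant_leaves(hypernym)
    if not leaves:
        raise VocabularyError(f"{hypernym!r} has no descendant leaves")
    if len(leaves) == 1:
        return 1.0
    vectors = []
    for leaf in leaves:
        emb = graph.get(leaf).embedding
        if emb is None:
            raise EmbeddingError(f"leaf {leaf!r} has no embedding")
        vectors.append(np.asarray(emb, dtype=float))
    mat = np.vstack(vectors)
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise EmbeddingError(f"zero-norm embedding under hypernym {hypernym!r}")
    unit = mat / norms[:, None]
    sims = [float(unit[i] @ unit[j]) for i, j in itertools.combinations(range(len(leaves)), 2)]
    return float(np.mean(sims))


@dataclass(frozen=True)
class HypernymMap:
    """Leaf concept → hypernym concept abstraction map.

    Every value is an ancestor (or the leaf itself) flagged ``is_hypernym``.
    ``unmapped`` lists leaves with no hypernym ancestor at all; these must
    never be exported.
    """

    entries: Mapping[str, str]
    similarity_threshold: float
    warnings: tuple[str, ...] = ()
    unmapped: tuple[str, ...] = ()

    def hypernym_for(self, leaf: str) -> Optional[str]:
        return self.entries.get(leaf)

    @property
    def allowed_hypernyms(self) -> frozenset[str]:
        return frozenset(self.entries.values())


def build_hypernym_map(graph: ConceptGraph, threshold: float = 0.7) -> HypernymMap:
    """Assign each leaf its exportable hypernym expression.

    A leaf maps to its most specific (deepest) hypernym ancestor whose leaf
    cohesion meets ``threshold``; depth ties break to the lexicographically
    smallest id.  When no candidate is cohesive enough the leaf falls back to
    its most general hypernym ancestor with a low-cohesion warning, so that a
    stricter threshold can only ever generalize further.  Leaves with no
    hypernym ancestor are reported as unmapped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise VocabularyError(f"threshold must lie in [0,1], got {threshold}")
    sim_cache: dict[str, Optional[float]] = {}
    warnings: list[str] = []

    def cohesion(hyp: str) -> Optional[float]:
        if hyp not in sim_cache:
            try:
                sim_cache[hyp] = leaf_similarity(graph, hyp)
            except EmbeddingError:
                sim_cache[hyp] = None
                warnings.append(f"hypernym {hyp!r}: cohesion unknown (missing embeddings)")
        return sim_cache[hyp]

    entries: dict[str, str] = {}
    unmapped: list[str] = []
    for leaf in graph.leaves:
        candidates = sorted(
            c
            for c in graph.ancestors(leaf, include_self=True)
            if graph.get(c).is_hypernym
        )
        if not candidates:
            unmapped.append(leaf)
            continue
        qualifying = [c for c in candidates
                      if (s := cohesion(c)) is not None and s >= threshold]
        if qualifying:
            chosen = min(qualifying, key=lambda c: (-graph.depth(c), c))
        else:
            chosen = min(candidates, key=lambda c: (graph.depth(c), c))
            warnings.append(
                f"leaf {leaf!r}: no hypernym met cohesion {threshold}; "
                f"fell back to most general {chosen!r}"
            )
        entries[leaf] = chosen
    return HypernymMap(
        entries=entries,
        similarity_threshold=threshold,
        warnings=tuple(warnings),
        unmapped=tuple(unmapped),
    )
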