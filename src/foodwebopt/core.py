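"""Food-web data model, graph utilities and plain-text I/O.

A food web is stored as a directed acyclic graph whose edges point in the
direction of energy flow, resource -> consumer.  Cannibalism (self-links) and
feeding loops are outside the model and are reported by :func:`validate_web`.

Connectance follows the directed convention C = L / n**2, the same quantity
the niche-model generator targets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "FoodWeb",
    "FoodWebError",
    "ValidationReport",
    "validate_web",
    "connectance",
    "basal_species",
    "trophic_levels",
    "read_web",
    "write_web",
]


class FoodWebError(ValueError):
    """Raised for malformed food-web files or operations on invalid webs."""


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_web`; violations are data, not exceptions."""

    is_valid: bool
    violations: tuple[str, ...]


class FoodWeb:
    """An immutable directed trophic network.

    Parameters
    ----------
    species_ids
        Ordered species labels.  Order is preserved; wherever a deterministic
        order is needed downstream, lexicographic label order is used.
    links
        Iterable of ``(resource, consumer)`` pairs.
    """

    __slots__ = ("species_ids", "links", "_graph", "_prey", "_pred")

    def __init__(self, species_ids: Iterable[str], links: Iterable[tuple[str, str]]):
        ids = tuple(str(s) for s in species_ids)
        if len(set(ids)) != len(ids):
            raise FoodWebError("duplicate species labels")
        object.__setattr__(self, "species_ids", ids)
        object.__setattr__(
            self, "links", frozenset((str(r), str(c)) for r, c in links)
        )
        object.__setattr__(self, "_graph", None)
        object.__setattr__(self, "_prey", None)
        object.__setattr__(self, "_pred", None)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("FoodWeb is immutable")

    @property
    def n(self) -> int:
        return len(self.species_ids)

    @property
    def L(self) -> int:
        return len(self.links)

    def graph(self) -> nx.DiGraph:
        """Directed graph view (resource -> consumer), cached."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.species_ids)
            g.add_edges_from(self.links)
            object.__setattr__(self, "_graph", g)
        return self._graph

    def _adjacency(self):
        if self._prey is None:
            prey: dict[str, list[str]] = {s: [] for s in self.species_ids}
            pred: dict[str, list[str]] = {s: [] for s in self.species_ids}
            for r, c in sorted(self.links):
                if c in prey:
                    prey[c].append(r)
                if r in pred:
                    pred[r].append(c)
            object.__setattr__(self, "_prey", {k: tuple(v) for k, v in prey.items()})
            object.__setattr__(self, "_pred", {k: tuple(v) for k, v in pred.items()})
        return self._prey, self._pred

    def prey_of(self, species: str) -> tuple[str, ...]:
        """Resources of *species*, in lexicographic order."""
        return self._adjacency()[0][species]

    def predators_of(self, species: str) -> tuple[str, ...]:
        """Consumers of *species*, in lexicographic order."""
        return self._adjacency()[1][species]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FoodWeb)
            and set(self.species_ids) == set(other.species_ids)
            and self.links == other.links
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.species_ids), self.links))

    def __repr__(self) -> str:
        return f"FoodWeb(n={self.n}, L={self.L})"


def validate_web(web: FoodWeb) -> ValidationReport:
    """Check the four structural invariants of the trophic model.

    Checks, in order: every link endpoint is a declared species, no self-links
    (cannibalism), no directed cycles, and at least one basal species when the
    web is non-empty.
    """
    violations: list[str] = []
    declared = set(web.species_ids)
    for r, c in sorted(web.links):
        if r not in declared or c not in declared:
            violations.append(f"unknown-endpoint: ({r}, {c})")
    for r, c in sorted(web.links):
        if r == c:
            violations.append(f"self-link: {r}")
    known_links = [
        (r, c) for r, c in web.links if r in declared and c in declared and r != c
    ]
    g = nx.DiGraph()
    g.add_nodes_from(web.species_ids)
    g.add_edges_from(known_links)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        violations.append("cycle: " + "->".join(e[0] for e in cyc) + "->" + cyc[-1][1])
    if web.n >= 1 and all(g.in_degree(s) > 0 for s in web.species_ids):
        violations.append("no-basal: every species has prey")
    return ValidationReport(is_valid=not violations, violations=tuple(violations))


def connectance(web: FoodWeb) -> float:
    """Directed connectance C = L / n**2."""
    if web.n < 1:
        raise FoodWebError("connectance undefined for an empty web")
    return web.L / web.n**2


def basal_species(web: FoodWeb) -> set[str]:
    """Species with no prey (primary producers)."""
    return {s for s in web.species_ids if not web.prey_of(s)}


def trophic_levels(web: FoodWeb) -> dict[str, int]:
    """Discrete longest-chain trophic level: basal species are level 1,
    every consumer sits one level above its highest-level prey."""
    g = web.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise FoodWebError("trophic levels undefined for a cyclic web")
    levels: dict[str, int] = {}
    for s in nx.topological_sort(g):
        prey = web.prey_of(s)
        levels[s] = 1 if not prey else 1 + max(levels[p] for p in prey)
    return levels


# ---------------------------------------------------------------------------
# I/O
#
# Edge-list CSV: header `resource,consumer`, one link per row.  Note that a
# species with no links cannot be represented in this dialect; the adjacency
# dialect preserves all species.
# Adjacency matrix: whitespace-delimited text; first row lists the species
# labels (columns = consumer), each following row is a species label (row =
# resource) followed by n entries in {0, 1}.
# ---------------------------------------------------------------------------

_FORMATS = ("edge_list", "adjacency")


def read_web(path, format: str = "edge_list", validate: bool = True) -> FoodWeb:
    """Read a food web from a plain-text file.

    Raises :class:`FoodWebError` for an unknown format, a malformed row
    (reported with its line number) or, when *validate* is true, a web that
    fails :func:`validate_web`.
    """
    if format == "edge_list":
        web = _read_edge_list(path)
    elif format == "adjacency":
        web = _read_adjacency(path)
    else:
        raise FoodWebError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if validate:
        report = validate_web(web)
        if not report.is_valid:
            raise FoodWebError(
                f"invalid web in {path}: " + "; ".join(report.violations)
            )
    return web


def write_web(web: FoodWeb, path, format: str = "edge_list") -> None:
    """Write a food web; inverse of :func:`read_web` up to species ordering."""
    if format == "edge_list":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["resource", "consumer"])
            writer.writerows(sorted(web.links))
    elif format == "adjacency":
        ids = sorted(web.species_ids)
        with open(path, "w") as fh:
            fh.write(" ".join(ids) + "\n")
            for r in ids:
                row = ["1" if (r, c) in web.links else "0" for c in ids]
                fh.write(r + " " + " ".join(row) + "\n")
    else:
        raise FoodWebError(f"unknown format {format!r}; expected one of {_FORMATS}")


def _read_edge_list(path) -> FoodWeb:
    links: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FoodWebError(f"{path}: empty edge-list file") from None
        if [h.strip().lower() for h in header] != ["resource", "consumer"]:
            raise FoodWebError(
                f"{path}: line 1: expected header 'resource,consumer', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) != 2 or not row[0].strip() or not row[1].strip():
                raise FoodWebError(
                    f"{path}: line {lineno}: expected two fields, got {row!r}"
                )
            links.append((row[0].strip(), row[1].strip()))
    species = sorted({s for link in links for s in link})
    return FoodWeb(species, links)


def _read_adjacency(path) -> FoodWeb:
    with open(path) as fh:
        lines = [ln for ln in (raw.strip() for raw in fh) if ln]
    if not lines:
        raise FoodWebError(f"{path}: empty adjacency file")
    labels = lines[0].split()
    n = len(labels)
    if len(lines) - 1 != n:
        raise FoodWebError(
            f"{path}: expected {n} matrix rows after the header, got {len(lines) - 1}"
        )
    links: list[tuple[str, str]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        tokens = ln.split()
        if len(tokens) != n + 1:
            raise FoodWebError(
                f"{path}: line {lineno}: expected label plus {n} entries, "
                f"got {len(tokens)} tokens"
            )
        row_label = tokens[0]
        for c_label, entry in zip(labels, tokens[1:]):
            if entry not in ("0", "1"):
                raise FoodWebError(
                    f"{path}: line {lineno}: matrix entries must be 0 or 1, "
                    f"got {entry!r}"
                )
            if entry == "1":
                links.append((row_label, c_label))
    return FoodWeb(labels, links)


def adjacency_matrix(web: FoodWeb, order: Iterable[str] | None = None):
    """0/1 numpy adjacency (rows = resource, columns = consumer)."""
    import numpy as np

    ids = list(order) if order is not None else sorted(web.species_ids)
    index: Mapping[str, int] = {s: i for i, s in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=int)
    for r, c in web.links:
        m[index[r], index[c]] = 1
    return m
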