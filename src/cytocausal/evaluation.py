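"""Ranked precision of causal predictions against a pathway ground truth.

The ground truth is a set of directed *ancestry* relations (cause,
effect) among the measured proteins — direct or indirect, as mined from
a pathway database such as KEGG.  It can be loaded from a two-column
edge list (TSV) or from minimal KGML pathway files; in either case the
transitive closure is applied, since a prediction counts as correct
when any directed path connects cause to effect.

Precision is reported along the prediction ranking (top-k precision for
every k), together with the precision of each prediction's *reverse*
pair — a diagnostic for systematically flipped orientations, e.g. from
feedback over time.  Significance against chance uses random prediction
sets of the same size and a one-sided z-test.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryTruth",
    "PrecisionCurve",
    "load_truth",
    "load_truth_kgml",
    "precision_at_rank",
    "random_baseline_test",
    "all_ordered_pairs",
]

# KGML relation subtypes treated as directed cause -> effect links; only
# the direction (not the sign) of a relation matters for ancestry.
CAUSAL_SUBTYPES = {"activation", "inhibition", "phosphorylation"}


@dataclass(frozen=True)
class AncestryTruth:
    """Transitively closed set of directed (cause, effect) relations."""

    pairs: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.pairs):
            raise ValueError("self-pairs are not valid ancestry relations")

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def _closure(pairs: set[tuple[str, str]]) -> frozenset[tuple[str, str]]:
    g = nx.DiGraph(pairs)
    closed = nx.transitive_closure(g, reflexive=False)
    return frozenset((u, v) for u, v in closed.edges() if u != v)


def _apply_aliases(name: str, aliases: dict[str, str] | None) -> str:
    return aliases.get(name, name) if aliases else name


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping file names to canonical marker names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def load_truth(
    path: str | Path, aliases: dict[str, str] | None = None
) -> AncestryTruth:
    """Load ancestry relations from a two-column (cause, effect) TSV.

    Cycles are allowed — closure is taken over the digraph, not a DAG.
    An empty file yields an empty truth with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty ground-truth file")
        return AncestryTruth(frozenset(), provenance=str(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns (cause, effect)")
    pairs = {
        (_apply_aliases(str(u), aliases), _apply_aliases(str(v), aliases))
        for u, v in zip(df[0], df[1])
        if str(u) != str(v)
    }
    return AncestryTruth(_closure(pairs), provenance=str(path))


def load_truth_kgml(
    paths: list[str | Path],
    aliases: dict[str, str] | None = None,
    keep_names: set[str] | None = None,
) -> AncestryTruth:
    """Extract directed relations from minimal KGML pathway files.

    Supports ``relation`` elements whose subtype is one of
    ``activation``, ``inhibition`` or ``phosphorylation``; entry ids are
    resolved to (the first of) their entry names.  Unmapped or filtered
    names are reported via logging.
    """
    pairs: set[tuple[str, str]] = set()
    for path in paths:
        path = Path(path)
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:
            raise ValueError(f"{path}: malformed KGML ({exc})") from exc
        names: dict[str, str] = {}
        for entry in root.iter("entry"):
            name = entry.get("name", "").split()[0] if entry.get("name") else ""
            names[entry.get("id", "")] = name
        for rel in root.iter("relation"):
            subtypes = {st.get("name") for st in rel.iter("subtype")}
            if not subtypes & CAUSAL_SUBTYPES:
                continue
            u = _apply_aliases(names.get(rel.get("entry1", ""), ""), aliases)
            v = _apply_aliases(names.get(rel.get("entry2", ""), ""), aliases)
            if not u or not v or u == v:
                logger.info("%s: skipping relation %s -> %s", path.name, u, v)
                continue
            if keep_names is not None and (u not in keep_names or v not in keep_names):
                continue
            pairs.add((u, v))
    return AncestryTruth(_closure(pairs), provenance=";".join(str(p) for p in paths))


@dataclass(frozen=True)
class PrecisionCurve:
    """Top-k precision of a ranked prediction list, forward and reversed."""

    ranked_pairs: tuple[tuple[str, str], ...]
    precision: tuple[float, ...]
    reversed_precision: tuple[float, ...]

    def at(self, k: int) -> float:
        if not (1 <= k <= len(self.precision)):
            raise ValueError(f"k={k} outside [1, {len(self.precision)}]")
        return self.precision[k - 1]


def precision_at_rank(
    ranked_pairs: list[tuple[str, str]], truth: AncestryTruth
) -> PrecisionCurve:
    """Precision of the top-k predictions for every k.

    The reversed curve scores each prediction's reverse pair against the
    truth; a pair whose forward and reverse relations are both true
    counts toward both curves.
    """
    if not ranked_pairs:
        raise ValueError("ranked prediction list is empty")
    fwd_hits = np.cumsum([pair in truth for pair in ranked_pairs])
    rev_hits = np.cumsum([(pair[1], pair[0]) in truth for pair in ranked_pairs])
    ks = np.arange(1, len(ranked_pairs) + 1)
    return PrecisionCurve(
        ranked_pairs=tuple(ranked_pairs),
        precision=tuple(fwd_hits / ks),
        reversed_precision=tuple(rev_hits / ks),
    )


def all_ordered_pairs(labels: list[str]) -> list[tuple[str, str]]:
    """The p * (p - 1) ordered (cause, effect) pairs over a marker set."""
    return [(u, v) for u in labels for v in labels if u != v]


@dataclass(frozen=True)
class BaselineTestResult:
    observed_precision: float
    baseline_mean: float
    baseline_sd: float
    z: float
    p_value: float
    n_rep: int


def random_baseline_test(
    predictions: list[tuple[str, str]],
    truth: AncestryTruth,
    universe: list[tuple[str, str]],
    n_rep: int = 10,
    seed: int | np.random.Generator | None = None,
) -> BaselineTestResult:
    """One-sided z-test of overall precision against random predictions.

    Draws ``n_rep`` random prediction sets of the same size from the
    ordered-pair universe and standardizes the observed precision by
    their mean and standard deviation.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be at least 2")
    if not predictions:
        raise ValueError("no predictions to test")
    rng = np.random.default_rng(seed)
    observed = float(np.mean([pair in truth for pair in predictions]))
    k = len(predictions)
    baseline = []
    for _ in range(n_rep):
        idx = rng.choice(len(universe), size=min(k, len(universe)), replace=False)
        baseline.append(float(np.mean([universe[int(i)] in truth for i in idx])))
    base = np.asarray(baseline)
    sd = float(base.std(ddof=1))
    if sd == 0:
        warnings.warn("zero variance across random prediction sets; p at boundary")
        z = np.inf if observed > base.mean() else -np.inf
        p = 0.0 if observed > base.mean() else 1.0
    else:
        z = float((observed - base.mean()) / sd)
        p = float(stats.norm.sf(z))
    return BaselineTestResult(observed, float(base.mean()), sd, z, p, n_rep)
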