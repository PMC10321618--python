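"""Fair-proportion evolutionary distinctness (ED) and EDGE scores.

ED of a tip is the sum, over the branches on its root-to-tip path, of the
branch length divided by the number of tips descending from that branch
("fair proportion"). ED values over all tips sum exactly to the total
branch length of the tree.

EDGE combines ED with the threat level (GE) of a species. Two functional
forms are implemented, selected by the extinction-probability scheme:

* ``isaac``        — EDGE = ln(1 + ED) + GE * ln 2, with GE the integer
                     rank of the IUCN category (LC=0 ... CR=4). This is
                     equivalent to ln((1+ED) * p) up to an additive
                     constant under category-doubling extinction
                     probabilities.
* ``iucn50/100/500`` — EDGE = ED * p(category), the expected loss of
                     unique evolutionary history under the category ->
                     extinction-probability transformations for a 50, 100
                     or 500 year horizon.

Within a scheme both forms are strictly monotone in ED and in category
severity, so priority rankings do not depend on the exact probability
constants; the constants shipped here are the conventional horizon
transformations and can be overridden per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import pandas as pd

from .tree import TreeError

__all__ = [
    "CATEGORIES",
    "THREATENED",
    "GE_RANK",
    "ExtinctionScheme",
    "SCHEMES",
    "ge_rank",
    "fair_proportion_ed",
    "edge_score",
    "ed_table",
    "edge_table",
    "read_status_table",
    "summarize_statuses",
]

#: Evaluated IUCN categories in increasing severity; NE = not evaluated.
CATEGORIES = ("LC", "NT", "VU", "EN", "CR")
THREATENED = ("VU", "EN", "CR")
NOT_EVALUATED = "NE"

GE_RANK = {cat: i for i, cat in enumerate(CATEGORIES)}


def ge_rank(category: str) -> int:
    """Integer threat rank: LC=0, NT=1, VU=2, EN=3, CR=4."""
    try:
        return GE_RANK[category]
    except KeyError:
        raise ValueError(
            f"no GE rank for category {category!r}; evaluated categories are "
            f"{'/'.join(CATEGORIES)}"
        ) from None


@dataclass(frozen=True)
class ExtinctionScheme:
    """A named category -> extinction-probability transformation.

    For ``kind='rank'`` (the Isaac scheme) the probabilities are implied by
    GE rank doubling and EDGE uses the log form; for ``kind='probability'``
    EDGE is the expected loss ED * p.
    """

    name: str
    kind: str  # 'rank' or 'probability'
    probabilities: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rank", "probability"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "probability":
            p = self.probabilities
            if p is None or set(p) != set(CATEGORIES):
                raise ValueError(
                    f"scheme {self.name!r} must assign a probability to every "
                    f"category {CATEGORIES}"
                )
            vals = [p[c] for c in CATEGORIES]
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError(f"scheme {self.name!r}: probabilities outside [0,1]")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"scheme {self.name!r}: probabilities must be non-decreasing "
                    "from LC to CR"
                )

    def score(self, ed: float, category: str) -> float:
        if ed < 0:
            raise ValueError("ED must be non-negative")
        if self.kind == "rank":
            return math.log1p(ed) + ge_rank(category) * math.log(2.0)
        return ed * self.probabilities[category]


def _horizon(name: str, lc, nt, vu, en, cr) -> ExtinctionScheme:
    return ExtinctionScheme(
        name,
        "probability",
        dict(zip(CATEGORIES, (lc, nt, vu, en, cr))),
    )


#: Default schemes. The 100-year probabilities are the conventional
#: transformation (CR 0.999, EN 2/3, VU 0.1, NT 0.01, LC 0.0001); the 50-
#: and 500-year tables extrapolate them as 1 - (1-p)^(h/100).
SCHEMES: dict[str, ExtinctionScheme] = {
    "isaac": ExtinctionScheme("isaac", "rank"),
    "iucn50": _horizon("iucn50", 0.00005, 0.005, 0.0513, 0.4226, 0.9684),
    "iucn100": _horizon("iucn100", 0.0001, 0.01, 0.1, 0.6667, 0.999),
    "iucn500": _horizon("iucn500", 0.0005, 0.049, 0.4095, 0.9959, 1.0),
}


def edge_score(ed: float, category: str, scheme: ExtinctionScheme | str) -> float:
    """EDGE of one species from its ED and IUCN category under *scheme*."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    return scheme.score(ed, category)


def fair_proportion_ed(tree: dendropy.Tree) -> pd.Series:
    """Fair-proportion ED for every tip of *tree*.

    Each branch contributes ``length / n_descendant_tips`` to every tip
    below it; the root edge (length treated as 0) is excluded. Polytomies
    are handled naturally. The returned Series is indexed by tip label.
    """
    n_tips: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        n_tips[node] = 1 if node.is_leaf() else sum(
            n_tips[c] for c in node.child_nodes()
        )
    acc: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    scores: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            acc[node] = acc[node.parent_node] + (node.edge.length or 0.0) / n_tips[node]
        if node.is_leaf():
            scores[node.taxon.label] = acc[node]
    return pd.Series(scores, name="ED")


def _score_table(per_replicate: list[pd.Series], metric: str) -> pd.DataFrame:
    table = pd.concat(
        {f"rep_{i:03d}": s for i, s in enumerate(per_replicate)}, axis=1
    )
    if table.isna().any().any():
        missing = table.index[table.isna().any(axis=1)].tolist()
        raise TreeError(f"species missing from some replicates: {missing}")
    table.insert(0, "median", table.median(axis=1))
    table.attrs["metric"] = metric
    table.index.name = "species"
    return table


def ed_table(replicates: list[dendropy.Tree]) -> pd.DataFrame:
    """Per-species ED across replicate trees, with a leading median column."""
    if not replicates:
        raise ValueError("no replicate trees supplied")
    return _score_table([fair_proportion_ed(t) for t in replicates], "ED")


def edge_table(
    replicates: list[dendropy.Tree],
    statuses: pd.Series,
    scheme: ExtinctionScheme | str,
) -> pd.DataFrame:
    """Per-species EDGE across replicates for evaluated species.

    *statuses* maps species to IUCN categories; species with category NE
    (or DD) are excluded from the output. Species listed in *statuses* but
    absent from the trees are reported via ``result.attrs['missing']``
    rather than raised.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if not replicates:
        raise ValueError("no replicate trees supplied")
    evaluated = statuses[statuses.isin(CATEGORIES)]
    tips = {leaf.taxon.label for leaf in replicates[0].leaf_node_iter()}
    missing = sorted(set(evaluated.index) - tips)
    evaluated = evaluated[evaluated.index.isin(tips)]
    cols = []
    for t in replicates:
        ed = fair_proportion_ed(t)
        cols.append(
            pd.Series(
                {
                    sp: scheme.score(ed[sp], cat)
                    for sp, cat in evaluated.items()
                },
            )
        )
    table = _score_table(cols, "EDGE")
    table.attrs["scheme"] = scheme.name
    table.attrs["missing"] = missing
    return table


def read_status_table(path) -> pd.Series:
    """Read a ``species,category`` CSV into a Series of categories.

    Underscores in species names are normalized to spaces; the DD (data
    deficient) category is treated as NE.
    """
    df = pd.read_csv(path)
    if not {"species", "category"} <= set(df.columns):
        raise ValueError("status table needs 'species' and 'category' columns")
    species = df["species"].str.replace("_", " ").str.strip()
    if species.duplicated().any():
        dupes = species[species.duplicated()].tolist()
        raise ValueError(f"duplicate species in status table: {dupes}")
    cats = df["category"].str.strip().str.upper().replace({"DD": NOT_EVALUATED})
    bad = sorted(set(cats) - set(CATEGORIES) - {NOT_EVALUATED})
    if bad:
        raise ValueError(f"unknown categories in status table: {bad}")
    return pd.Series(cats.values, index=species.values, name="category")


def summarize_statuses(statuses: pd.Series) -> pd.DataFrame:
    """Counts and whole-percent shares per evaluated category, plus a
    threatened (VU+EN+CR) total; percentages are relative to the number of
    evaluated species."""
    evaluated = statuses[statuses.isin(CATEGORIES)]
    n = len(evaluated)
    rows = {}
    for cat in reversed(CATEGORIES):  # CR first, as usually tabulated
        count = int((evaluated == cat).sum())
        rows[cat] = (count, round(100.0 * count / n) if n else float("nan"))
    threatened = int(evaluated.isin(THREATENED).sum())
    rows["threatened"] = (threatened, round(100.0 * threatened / n) if n else float("nan"))
    rows["evaluated"] = (n, 100)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["count", "percent"]
    )
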