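"""AP-MS co-purification matrices and deletion-dependency inference.

Input is a unique-peptide count matrix over (bait, genetic background,
prey): each tagged bait is affinity-purified from a wild-type background
and from one or more deletion backgrounds, and every co-recovered prey is
quantified by its number of unique peptides.  Two operations mirror the
standard interpretation of such matrices:

* specificity filtering -- any prey also recovered in the no-tag control
  purification is discarded everywhere;
* deletion-dependency inference -- a prey *requires* a gene for bait
  association when it is confidently present in the wild-type purification
  (>= ``min_peptides`` unique peptides) and absent (0 peptides) when that
  gene is deleted.  Mutually-dependent proteins (a requires b and b
  requires a) define candidate protein modules: connected components of the
  mutual-dependency graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "PeptideMatrix",
    "DependencyEdge",
    "filter_nonspecific",
    "infer_dependencies",
    "mutual_modules",
    "edges_to_dot",
    "EDGE_COLUMNS",
]

EDGE_COLUMNS = ["prey", "bait", "requires", "count_wt", "count_del"]


@dataclass(frozen=True)
class DependencyEdge:
    """Prey requires a gene (deletion label) for association with a bait."""

    prey: str
    bait: str
    requires: str
    count_wt: int
    count_del: int


class PeptideMatrix:
    """Unique-peptide counts keyed by (bait, background, prey).

    ``control_label`` names the no-tag purification among the baits;
    ``wildtype_label`` names the non-deletion background.  Counts absent
    from the table are zero.
    """

    def __init__(
        self,
        entries: pd.DataFrame,
        control_label: Optional[str] = "no_tag",
        wildtype_label: str = "wt",
    ):
        required = {"bait", "background", "prey", "unique_peptides"}
        if not required.issubset(entries.columns):
            raise ValueError(f"peptide table needs columns {sorted(required)}")
        df = entries.loc[:, ["bait", "background", "prey", "unique_peptides"]].copy()
        df["unique_peptides"] = df["unique_peptides"].astype(int)
        if (df["unique_peptides"] < 0).any():
            raise ValueError("unique-peptide counts must be non-negative")
        dup = df.duplicated(subset=["bait", "background", "prey"])
        if dup.any():
            raise ValueError("duplicate (bait, background, prey) entries")
        self.entries = df.sort_values(
            ["bait", "background", "prey"], kind="stable"
        ).reset_index(drop=True)
        self.control_label = control_label
        self.wildtype_label = wildtype_label

    @property
    def baits(self) -> list[str]:
        return sorted(b for b in self.entries["bait"].unique()
                      if b != self.control_label)

    @property
    def backgrounds(self) -> list[str]:
        return sorted(self.entries["background"].unique())

    @property
    def preys(self) -> list[str]:
        return sorted(self.entries["prey"].unique())

    def count(self, bait: str, background: str, prey: str) -> int:
        m = self.entries[
            (self.entries["bait"] == bait)
            & (self.entries["background"] == background)
            & (self.entries["prey"] == prey)
        ]
        return int(m["unique_peptides"].sum())

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "PeptideMatrix":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def filter_nonspecific(matrix: PeptideMatrix) -> PeptideMatrix:
    """Drop every prey also recovered in the no-tag control purification.

    Idempotent.  Raises when the matrix declares no control purification.
    """
    if matrix.control_label is None:
        raise ValueError("matrix has no control purification to filter against")
    df = matrix.entries
    in_control = df[
        (df["bait"] == matrix.control_label) & (df["unique_peptides"] >= 1)
    ]["prey"].unique()
    kept = df[~df["prey"].isin(in_control)]
    out = PeptideMatrix(
        kept, control_label=matrix.control_label,
        wildtype_label=matrix.wildtype_label,
    )
    out.removed_preys = sorted(in_control)  # logged removal list
    return out


def _normalize_gene_label(label: str) -> str:
    norm = label.lower().replace("Δ", "").replace("delta", "").replace(".", "")
    return norm.rstrip("_-")


def _deleted_gene_matches_prey(background: str, prey: str) -> bool:
    """Heuristic match of a deletion label to its protein among the preys."""
    return _normalize_gene_label(background) == _normalize_gene_label(prey)


def infer_dependencies(
    matrix: PeptideMatrix,
    min_peptides: int = 2,
    fold_drop: Optional[float] = None,
) -> pd.DataFrame:
    """Infer which preys require which genes for association with each bait.

    Default rule: prey present with >= ``min_peptides`` unique peptides in
    the wild-type purification of a bait and 0 peptides when gene g is
    deleted -> edge (prey requires g for that bait).  With ``fold_drop`` set
    the absence rule relaxes to ``count_del <= count_wt / fold_drop``.  The
    deleted gene's own protein is never reported as depending on itself.
    Returns a deterministic edge table (columns ``prey, bait, requires,
    count_wt, count_del``).
    """
    df = matrix.entries
    wt = matrix.wildtype_label
    rows = []
    for bait in matrix.baits:
        sub = df[df["bait"] == bait]
        backgrounds = set(sub["background"])
        if wt not in backgrounds:
            import warnings

            warnings.warn(
                f"bait {bait!r}: no wild-type purification; contrasts skipped",
                stacklevel=2,
            )
            continue
        wt_counts = (
            sub[sub["background"] == wt].set_index("prey")["unique_peptides"]
        )
        for bg in sorted(backgrounds - {wt}):
            del_counts = (
                sub[sub["background"] == bg].set_index("prey")["unique_peptides"]
            )
            for prey, c_wt in wt_counts.items():
                if c_wt < min_peptides:
                    continue
                if _deleted_gene_matches_prey(bg, prey):
                    continue
                c_del = int(del_counts.get(prey, 0))
                if fold_drop is None:
                    dependent = c_del == 0
                else:
                    dependent = c_del <= c_wt / fold_drop
                if dependent:
                    rows.append(
                        {
                            "prey": prey,
                            "bait": bait,
                            "requires": bg,
                            "count_wt": int(c_wt),
                            "count_del": c_del,
                        }
                    )
    return (
        pd.DataFrame(rows, columns=EDGE_COLUMNS)
        .sort_values(["prey", "bait", "requires"], kind="stable")
        .reset_index(drop=True)
    )


def mutual_modules(edges: pd.DataFrame, preys: Optional[list[str]] = None) -> list[set[str]]:
    """Candidate protein modules: components of the mutual-dependency graph.

    Two proteins a, b are mutually dependent when some edge says a requires
    deletion of b's gene and some edge says b requires deletion of a's gene
    (for any baits).  Components with >= 2 members are returned, sorted.
    """
    if preys is None:
        preys = sorted(set(edges["prey"]))
    requires: set[tuple[str, str]] = set()
    for row in edges.itertuples(index=False):
        for target in preys:
            if _deleted_gene_matches_prey(row.requires, target):
                requires.add((row.prey, target))
    mutual = {(a, b) for (a, b) in requires if (b, a) in requires and a != b}
    adjacency: dict[str, set[str]] = {}
    for a, b in mutual:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    seen: set[str] = set()
    modules = []
    for node in sorted(adjacency):
        if node in seen:
            continue
        component = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur in component:
                continue
            component.add(cur)
            stack.extend(adjacency.get(cur, ()))
        seen |= component
        if len(component) >= 2:
            modules.append(component)
    return modules


def edges_to_dot(edges: pd.DataFrame) -> str:
    """GraphViz DOT export of the dependency graph (prey -> required gene)."""
    lines = ["digraph dependencies {"]
    for row in edges.itertuples(index=False):
        lines.append(
            f'  "{row.prey}" -> "{row.requires}" '
            f'[label="bait={row.bait} {row.count_wt}/{row.count_del}"];'
        )
    lines.append("}")
    return "\n".join(lines)
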