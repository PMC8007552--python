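"""End-to-end analysis orchestration and report rendering.

``run_full_analysis`` chains the whole published workflow: parse/validate
the matrix, search for most parsimonious trees, compute ensemble fit
indices, Bremer support for every branch, root on the outgroup, map
ACCTRAN transformations, and collect synapomorphies for clades of
interest.  The resulting :class:`AnalysisReport` serializes to JSON and
writes Newick / TSV artifacts; ``render_annotated_tree`` draws an ASCII
cladogram with per-branch ``character(state)`` annotations flagged
``u``/``h`` for unique versus homoplastic changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple

from . import __version__
from .acctran import (
    AncestralAssignment,
    acctran_reconstruct,
    clade_synapomorphies,
    root_tree,
)
from .engine import FitStatistics, encode, fit_statistics
from .matrix_io import (
    CharacterMatrix,
    MatrixSummary,
    load_study_fixture,
    summarize,
    write_matrix,
)
from .search import (
    SearchConfig,
    SearchResult,
    branch_and_bound,
    exhaustive_search,
    heuristic_search,
)
from .support import SupportRecord, support_table
from .trees import TreeTopology

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "render_annotated_tree",
    "write_outputs",
]

#: The three clades with printed synapomorphy counts in the study.
STUDY_CLADES: Dict[str, FrozenSet[str]] = {
    "Sadocus": frozenset(
        {
            "Sadocus asperatus",
            "Sadocus dilatatus",
            "Sadocus funestus",
            "Sadocus ingens",
            "Sadocus polyacanthus",
        }
    ),
    "Sadocus+Neogonyleptes": frozenset(
        {
            "Sadocus asperatus",
            "Sadocus dilatatus",
            "Sadocus funestus",
            "Sadocus ingens",
            "Sadocus polyacanthus",
            "Neogonyleptes docilis",
            "Neogonyleptes karschii",
        }
    ),
    "Discocyrtus catharinensis+Roeweria bittencourti": frozenset(
        {"Discocyrtus catharinensis", "Roeweria bittencourti"}
    ),
}

STUDY_OUTGROUP = "Stygnus polyacanthus"


@dataclass(frozen=True)
class AnalysisConfig:
    """What to analyze and how.

    ``matrix`` defaults to the bundled study fixture; ``outgroup`` to the
    study outgroup when present, else the matrix's first taxon.
    """

    matrix: Optional[CharacterMatrix] = None
    outgroup: Optional[str] = None
    strategy: str = "auto"
    seed: int = 0
    n_replicates: int = 10
    compute_support: bool = True
    clades_of_interest: Optional[Dict[str, FrozenSet[str]]] = None


@dataclass
class AnalysisReport:
    """Everything the analysis produced, re-derivable from the provenance."""

    summary: MatrixSummary
    search: SearchResult
    fit: FitStatistics
    support: List[SupportRecord]
    rooted_tree: TreeTopology
    assignment: AncestralAssignment
    synapomorphies: Dict[str, List]
    provenance: Dict[str, object]

    def to_dict(self) -> Dict[str, object]:
        return {
            "matrix": {
                "n_taxa": self.summary.n_taxa,
                "n_characters": self.summary.n_characters,
                "n_parsimony_informative": self.summary.n_parsimony_informative,
                "n_missing": self.summary.n_missing,
                "n_inapplicable": self.summary.n_inapplicable,
            },
            "search": {
                "best_length": self.search.best_length,
                "n_optimal_trees": len(self.search.optimal_trees),
                "proven_optimal": self.search.proven_optimal,
                "trees": [t.newick() for t in self.search.optimal_trees],
            },
            "fit": self.fit.to_dict(),
            "support": [
                {
                    "clade": sorted(r.clade),
                    "absolute_bremer": r.absolute_bremer,
                    "relative_bremer": r.relative_bremer,
                }
                for r in self.support
            ],
            "rooted_tree": self.rooted_tree.newick(),
            "transformations": [
                {
                    "branch": sorted(r.branch),
                    "character": r.character,
                    "from_state": r.from_state,
                    "to_state": r.to_state,
                    "uniqueness": r.uniqueness,
                }
                for r in self.assignment.transformations
            ],
            "synapomorphies": {
                name: [
                    {
                        "character": r.character,
                        "from_state": r.from_state,
                        "to_state": r.to_state,
                        "uniqueness": r.uniqueness,
                    }
                    for r in recs
                ]
                for name, recs in self.synapomorphies.items()
            },
            "provenance": self.provenance,
        }


def run_full_analysis(config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Run search, fit statistics, Bremer support, rooting and ACCTRAN
    mapping; see module docstring."""
    matrix = config.matrix if config.matrix is not None else load_study_fixture()
    outgroup = config.outgroup
    if outgroup is None:
        outgroup = (
            STUDY_OUTGROUP if STUDY_OUTGROUP in matrix.taxa else matrix.taxa[0]
        )
    if outgroup not in matrix.taxa:
        raise ValueError(f"outgroup {outgroup!r} is not in the matrix")
    enc = encode(matrix)
    strategy = config.strategy
    if strategy == "auto":
        # exact proof cost explodes with taxa and homoplasy; beyond this
        # scale independent heuristic batches are the practical route
        strategy = "branch_and_bound" if enc.n_taxa <= 14 else "heuristic"
    if strategy in ("branch_and_bound", "exhaustive") and enc.n_taxa > 25:
        raise ValueError(
            f"exact search over {enc.n_taxa} taxa is infeasible; "
            "use strategy='heuristic'"
        )

    search_config = SearchConfig(
        strategy=strategy,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )
    if strategy == "heuristic":
        search = heuristic_search(enc, search_config)
    elif strategy == "exhaustive":
        search = exhaustive_search(enc)
    else:
        search = branch_and_bound(enc, config=search_config)

    mpt = search.optimal_trees[0]
    fit = fit_statistics(mpt, enc, matrix)
    support: List[SupportRecord] = []
    if config.compute_support:
        method = "auto" if search.proven_optimal else "tree_set"
        support = support_table(enc, search, method=method)

    # mapping needs a binary tree: use the (first) MPT; with several
    # optima the consensus is still reported through the search digest
    rooted = root_tree(mpt, outgroup)
    assignment = acctran_reconstruct(rooted, enc)

    clades = config.clades_of_interest
    if clades is None:
        clades = {
            name: members
            for name, members in STUDY_CLADES.items()
            if members <= frozenset(matrix.taxa)
        }
    synapomorphies = {}
    for name, members in clades.items():
        if members in assignment.states:
            synapomorphies[name] = clade_synapomorphies(assignment, members)
        else:
            synapomorphies[name] = []

    provenance = {
        "tool": "mptree",
        "version": __version__,
        "strategy": strategy,
        "seed": config.seed,
        "n_replicates": config.n_replicates,
        "outgroup": outgroup,
        "matrix_sha256": hashlib.sha256(
            write_matrix(matrix, "tsv").encode()
        ).hexdigest(),
    }
    return AnalysisReport(
        summary=summarize(matrix),
        search=search,
        fit=fit,
        support=support,
        rooted_tree=rooted,
        assignment=assignment,
        synapomorphies=synapomorphies,
        provenance=provenance,
    )


def render_annotated_tree(report: AnalysisReport) -> str:
    """ASCII cladogram of the rooted mapped tree.

    Each branch shows its ACCTRAN changes as ``character(state)`` tokens
    suffixed ``u`` (unique) or ``h`` (homoplastic).
    """
    assignment = report.assignment
    by_branch: Dict[FrozenSet[str], List[str]] = {}
    for rec in assignment.transformations:
        by_branch.setdefault(rec.branch, []).append(str(rec))

    def leafset(shape) -> FrozenSet[str]:
        if isinstance(shape, str):
            return frozenset([shape])
        return frozenset().union(*(leafset(k) for k in shape))

    def render(shape) -> Tuple[List[str], int]:
        ann = " ".join(by_branch.get(leafset(shape), []))
        tag = f"-[{ann}]-" if ann else "--"
        if isinstance(shape, str):
            return [f"{tag} {shape}"], 0
        blocks = [render(k) for k in shape]
        lines: List[str] = []
        mids: List[int] = []
        for bi, (blines, bmid) in enumerate(blocks):
            if bi > 0:
                lines.append("|")
            mids.append(len(lines) + bmid)
            lines.extend(blines)
        top, bottom = mids[0], mids[-1]
        out: List[str] = []
        for i, line in enumerate(lines):
            if i == top:
                lead = "/" if len(mids) > 1 else "-"
            elif i == bottom:
                lead = "\\"
            elif i in mids:
                lead = "+"
            elif top < i < bottom:
                lead = "|"
            else:
                lead = " "
            out.append(lead + line)
        mid = (top + bottom) // 2
        final: List[str] = []
        pad = " " * len(tag)
        for i, line in enumerate(out):
            prefix = tag if i == mid else pad
            if i == mid and top < mid < bottom and line[0] == "|":
                line = "+" + line[1:]
            final.append(prefix + line)
        return final, mid

    lines, _ = render(report.rooted_tree.shape)
    return "\n".join(lines)


def write_outputs(report: AnalysisReport, outdir: Path) -> Dict[str, Path]:
    """Write the report artifacts: Newick trees, TSV tables, JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["trees"] = outdir / "mpt.nwk"
    paths["trees"].write_text(
        "".join(t.newick() + "\n" for t in report.search.optimal_trees)
    )
    paths["rooted"] = outdir / "rooted.nwk"
    paths["rooted"].write_text(report.rooted_tree.newick() + "\n")

    paths["support"] = outdir / "support.tsv"
    with open(paths["support"], "w") as f:
        f.write("clade\tabsolute_bremer\trelative_bremer\n")
        for r in report.support:
            rel = "" if r.relative_bremer is None else f"{r.relative_bremer:.3f}"
            f.write(f"{','.join(sorted(r.clade))}\t{r.absolute_bremer}\t{rel}\n")

    paths["steps"] = outdir / "character_steps.tsv"
    with open(paths["steps"], "w") as f:
        f.write("character\tsteps\tmin_steps\tmax_steps\n")
        for c, (s, m, g) in enumerate(
            zip(report.fit.steps, report.fit.minima, report.fit.maxima), 1
        ):
            f.write(f"{c}\t{s}\t{m}\t{g}\n")

    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report.to_dict(), indent=2) + "\n")

    paths["cladogram"] = outdir / "cladogram.txt"
    paths["cladogram"].write_text(render_annotated_tree(report) + "\n")
    return paths
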