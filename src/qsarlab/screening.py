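"""In-silico screening: bioisosteric enumeration, AD gating and ranking.

The screening stage mirrors the study workflow: take potent parents
(IC50 below a template threshold), enumerate bioisosteric variants —
by default replacing amide N–H groups with O (ester) or S (thioester) —
predict pIC50 with the chosen model, keep only candidates inside the
model's applicability domain, and rank the in-domain candidates by
predicted activity.  The AD gate reuses the applicability module's flags
verbatim; no thresholding logic is duplicated here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from networkx.algorithms.graph_hashing import weisfeiler_lehman_graph_hash

from .applicability import leverages
from .data import DescriptorTable
from .exceptions import SpecificationError
from .molgraph import MolecularGraph

log = logging.getLogger(__name__)

DEFAULT_ACTIVITY_FLOOR = 5.25      # pIC50 hit threshold
DEFAULT_TEMPLATE_IC50_UM = 9.0     # parent-selection cutoff, µM


def pic50_from_ic50_um(ic50_um: float) -> float:
    """pIC50 = −log10(IC50 in mol/L); input in µM (1 µM = 1e−6 mol/L)."""
    if ic50_um <= 0:
        raise SpecificationError("IC50 must be positive")
    return -math.log10(ic50_um * 1e-6)


def select_templates(ic50_um: dict[str, float],
                     threshold_um: float = DEFAULT_TEMPLATE_IC50_UM) -> list[str]:
    """Parents potent enough to seed screening (IC50 < threshold)."""
    return [cid for cid, v in ic50_um.items() if v < threshold_um]


# ---------------------------------------------------------------------------
# bioisosteric enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionRule:
    """Replace an element bearing ≥ min_h hydrogens by another element.

    The default rules swap amide-type N–H for O or S (ester/thioester
    bioisosteres); attached hydrogens at the site are removed so the new
    heteroatom keeps a sensible valence.
    """

    name: str
    match_element: str = "N"
    min_h: int = 1
    replacement: str = "O"


def default_rules() -> list[SubstitutionRule]:
    return [SubstitutionRule("NH->O", "N", 1, "O"),
            SubstitutionRule("NH->S", "N", 1, "S")]


@dataclass
class Candidate:
    graph: MolecularGraph
    parent_id: str
    rule: str
    site: int              # atom index in the parent


def _graph_key(g: MolecularGraph) -> str:
    G = g.to_networkx()
    for i in G.nodes:
        G.nodes[i]["label"] = f"{g.atoms[i].element}:{g.atoms[i].formal_charge}"
    for i, j in G.edges:
        G.edges[i, j]["elabel"] = str(G.edges[i, j]["order"])
    return weisfeiler_lehman_graph_hash(G, node_attr="label",
                                        edge_attr="elabel", iterations=3)


def _apply_rule(g: MolecularGraph, site: int,
                rule: SubstitutionRule) -> MolecularGraph:
    drop = {j for j in g.neighbors(site) if g.atoms[j].element == "H"}
    keep = [i for i in range(g.n_atoms) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        a = g.atoms[old]
        if old == site:
            a = dc_replace(a, element=rule.replacement)
        else:
            a = dc_replace(a)
        atoms.append(a)
    bonds = [(remap[i], remap[j], o) for i, j, o in g.bonds
             if i in remap and j in remap]
    return MolecularGraph(atoms, bonds)


def enumerate_bioisosteres(parent: MolecularGraph,
                           rules: list[SubstitutionRule] | None = None,
                           parent_id: str = "parent") -> list[Candidate]:
    """One candidate per (rule, matching site); duplicates canonicalized away.

    A rule that matches nothing contributes no candidates (logged, not an
    error).  The candidate set is independent of atom input order because
    duplicates are removed by a canonical (Weisfeiler-Lehman) graph hash.
    """
    if rules is None:
        rules = default_rules()
    seen: set[str] = set()
    out: list[Candidate] = []
    for rule in rules:
        sites = [i for i, a in enumerate(parent.atoms)
                 if a.element == rule.match_element
                 and sum(parent.atoms[j].element == "H"
                         for j in parent.neighbors(i)) >= rule.min_h]
        if not sites:
            log.info("rule %s matched no site in %s", rule.name, parent_id)
        for site in sites:
            g = _apply_rule(parent, site, rule)
            key = _graph_key(g)
            if key in seen:
                continue
            seen.add(key)
            out.append(Candidate(graph=g, parent_id=parent_id,
                                 rule=rule.name, site=site))
    return out


# ---------------------------------------------------------------------------
# AD-gated screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    candidate_id: str
    parent_id: str | None
    modification: str | None
    predicted_pic50: float
    leverage: float
    in_domain: bool
    is_hit: bool
    rank: int | None       # among in-domain candidates, 1 = best


def screen(model, candidates: DescriptorTable, training: DescriptorTable,
           activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
           provenance: pd.DataFrame | None = None) -> list[ScreeningResult]:
    """Predict, AD-gate and rank screening candidates.

    ``provenance`` may carry per-candidate ``parent_id`` and
    ``modification`` columns (indexed by candidate ID).  Hits are
    in-domain candidates with predicted pIC50 ≥ ``activity_floor``.
    Ranks (1 = highest prediction) cover exactly the in-domain
    candidates; out-of-domain candidates get none.
    """
    preds = np.asarray(model.predict(candidates), dtype=float)
    adr = leverages(model, training, candidates)
    cand_rows = adr.frame().loc[~adr.frame().is_training]

    ids = candidates.ids
    in_domain = cand_rows.loc[ids, "in_domain"].to_numpy()
    lev = cand_rows.loc[ids, "leverage"].to_numpy()

    order = np.argsort(-preds, kind="stable")
    ranks: dict[int, int] = {}
    next_rank = 1
    for idx in order:
        if in_domain[idx]:
            ranks[idx] = next_rank
            next_rank += 1

    results = []
    for idx, cid in enumerate(ids):
        parent = modification = None
        if provenance is not None and cid in provenance.index:
            parent = provenance.loc[cid].get("parent_id")
            modification = provenance.loc[cid].get("modification")
        results.append(ScreeningResult(
            candidate_id=cid, parent_id=parent, modification=modification,
            predicted_pic50=float(preds[idx]), leverage=float(lev[idx]),
            in_domain=bool(in_domain[idx]),
            is_hit=bool(in_domain[idx] and preds[idx] >= activity_floor),
            rank=ranks.get(idx)))
    results.sort(key=lambda r: (r.rank is None, r.rank if r.rank is not None
                                else -r.predicted_pic50))
    return results


def screening_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results]).set_index("candidate_id")
    return df
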