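"""Parsimony protein inference.

Re-maps identified peptides to a minimal, non-redundant set of protein groups:
proteins with identical peptide evidence merge into one group, proteins whose
evidence is a strict subset of another's are subsumed, proteins carrying at
least one unique peptide are kept as separate groups, and any remaining
peptides are covered greedily (largest number of unexplained peptides first,
ties broken by lexicographic accession).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass(frozen=True)
class ProteinGroup:
    group_id: str
    members: tuple[str, ...]          # accessions, sorted
    peptides: frozenset[str]
    has_unique_evidence: bool


@dataclass
class ProteinGroupSet:
    groups: list[ProteinGroup]
    peptide_assignment: dict[str, tuple[str, ...]]  # peptide -> group ids

    def group(self, group_id: str) -> ProteinGroup:
        return {g.group_id: g for g in self.groups}[group_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.group_id, ";".join(g.members), len(g.peptides),
                 g.has_unique_evidence)
                for g in self.groups
            ],
            columns=["group_id", "accessions", "n_peptides", "unique_evidence"],
        )


def build_incidence(pairs) -> dict[str, frozenset[str]]:
    """Deduplicated protein -> peptide-set incidence from (peptide, protein) pairs.

    Accepts an iterable of 2-tuples or a two-column DataFrame
    (peptide_id, protein).
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = list(zip(pairs.iloc[:, 0], pairs.iloc[:, 1]))
    pairs = sorted(set((str(p), str(a)) for p, a in pairs))
    if not pairs:
        raise ValueError("empty peptide-protein map")
    by_prot: dict[str, set[str]] = {}
    for pep, acc in pairs:
        by_prot.setdefault(acc, set()).add(pep)
    return {acc: frozenset(peps) for acc, peps in by_prot.items()}


def infer_protein_groups(incidence: dict[str, frozenset[str]]) -> ProteinGroupSet:
    """Minimal non-redundant protein grouping (merge, subsume, unique, greedy)."""
    # 1. merge proteins with identical peptide sets
    by_pepset: dict[frozenset[str], list[str]] = {}
    for acc in sorted(incidence):
        by_pepset.setdefault(incidence[acc], []).append(acc)
    candidates = [(tuple(sorted(accs)), peps) for peps, accs in by_pepset.items()]
    # 2. subsume strict subsets
    kept = []
    for members, peps in candidates:
        if any(peps < other for _, other in candidates):
            continue
        kept.append((members, peps))
    kept.sort(key=lambda t: t[0])

    all_peptides = frozenset().union(*incidence.values())
    pep_owners: dict[str, list[int]] = {p: [] for p in all_peptides}
    for i, (_, peps) in enumerate(kept):
        for p in peps:
            pep_owners[p].append(i)

    # 3. fix unique-evidence groups first — they can never be absorbed
    unique_idx = sorted({owners[0] for owners in pep_owners.values()
                         if len(owners) == 1})
    selected = list(unique_idx)
    explained: set[str] = set()
    for i in selected:
        explained |= kept[i][1]

    # 4. greedy cover of the remaining peptides
    remaining = [i for i in range(len(kept)) if i not in set(selected)]
    while explained != all_peptides:
        best, best_gain = None, 0
        for i in remaining:
            gain = len(kept[i][1] - explained)
            if gain > best_gain:  # ties resolved by lexicographic order of `kept`
                best, best_gain = i, gain
        if best is None:
            raise RuntimeError("uncoverable peptides (inconsistent incidence)")
        selected.append(best)
        remaining.remove(best)
        explained |= kept[best][1]

    selected.sort()
    groups = []
    for i in selected:
        members, peps = kept[i]
        uniq = any(len(pep_owners[p]) == 1 for p in peps)
        groups.append(ProteinGroup(";".join(members), members, peps, uniq))
    assignment: dict[str, tuple[str, ...]] = {}
    for p in sorted(all_peptides):
        assignment[p] = tuple(g.group_id for g in groups if p in g.peptides)
    return ProteinGroupSet(groups, assignment)


def minimal_cover_bruteforce(incidence: dict[str, frozenset[str]]) -> int:
    """Exact minimum number of proteins covering all peptides (test oracle).

    Exhaustive enumeration; refuses instances with more than 15 proteins.
    """
    prots = sorted(incidence)
    if len(prots) > 15:
        raise ValueError("brute-force cover limited to <= 15 proteins")
    universe = frozenset().union(*incidence.values()) if prots else frozenset()
    if not universe:
        return 0
    for k in range(1, len(prots) + 1):
        for combo in combinations(prots, k):
            cov = frozenset().union(*(incidence[a] for a in combo))
            if cov == universe:
                return k
    raise RuntimeError("unreachable: full set always covers")
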