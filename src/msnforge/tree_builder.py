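"""MS^n tree assembly.

Scans from one flow-injection file (one polarity, one "feature" per
precursor — no chromatographic deconvolution) are grouped into trees
rooted at MS^2 precursors. Lineage matching uses the scan's *full*
precursor chain, not just the immediate precursor, so isobaric ions at
deeper levels cannot cross-link trees from different root precursors.

The forest is order invariant: scans are internally sorted before
grouping, so a shuffled input yields an identical forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .msdata_io import ScanRecord

DEFAULT_MZ_TOL = 0.01  # Th; isolation widths are >= 1.2 Th so this is safely tight


@dataclass
class MsnTreeNode:
    """One precursor node: member scans of a shared lineage plus children."""

    node_precursor_mz: float  # TIC-weighted mean of member selection m/z
    ms_level: int
    member_scans: list[ScanRecord] = field(default_factory=list)
    children: list["MsnTreeNode"] = field(default_factory=list)
    orphan: bool = False

    def add_scan(self, scan: ScanRecord) -> None:
        self.member_scans.append(scan)
        self._update_mz()

    def _update_mz(self) -> None:
        num = den = 0.0
        for s in self.member_scans:
            w = s.tic or 1.0
            num += w * s.precursor_chain[-1].precursor_mz
            den += w
        self.node_precursor_mz = num / den

    def walk(self) -> Iterator["MsnTreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    @property
    def scan_count(self) -> int:
        return sum(len(n.member_scans) for n in self.walk())

    def energies(self) -> list[float]:
        return sorted({s.collision_energy for s in self.member_scans})

    def depth(self) -> int:
        return max(n.ms_level for n in self.walk())


def _sort_key(scan: ScanRecord):
    return (
        scan.ms_level,
        tuple(step.precursor_mz for step in scan.precursor_chain),
        scan.scan_number,
    )


def build_trees(scans: Sequence[ScanRecord], mz_tol: float = DEFAULT_MZ_TOL) -> list[MsnTreeNode]:
    """Group MS^>=2 scans into precursor-lineage trees.

    MS^2 scans whose selection m/z agree within ``mz_tol`` share a root;
    deeper scans attach where every stage of their precursor chain matches
    the path from the root within ``mz_tol``. Scans with no matching
    parent become flagged single-node orphan trees.
    """
    roots: list[MsnTreeNode] = []
    msn = sorted((s for s in scans if s.ms_level >= 2), key=_sort_key)
    for scan in msn:
        chain = scan.precursor_chain
        if scan.ms_level == 2:
            node = _find_node(roots, chain[0].precursor_mz, mz_tol)
            if node is None:
                node = MsnTreeNode(node_precursor_mz=chain[0].precursor_mz, ms_level=2)
                roots.append(node)
            node.add_scan(scan)
            continue
        # walk the chain from the root; all stages but the last must exist
        parent = _find_node((r for r in roots if not r.orphan), chain[0].precursor_mz, mz_tol)
        for step in chain[1:-1]:
            if parent is None:
                break
            parent = _find_node(parent.children, step.precursor_mz, mz_tol)
        if parent is None or parent.ms_level != scan.ms_level - 1:
            orphan = MsnTreeNode(
                node_precursor_mz=chain[-1].precursor_mz, ms_level=scan.ms_level, orphan=True
            )
            orphan.add_scan(scan)
            roots.append(orphan)
            continue
        node = _find_node(parent.children, chain[-1].precursor_mz, mz_tol)
        if node is None:
            node = MsnTreeNode(node_precursor_mz=chain[-1].precursor_mz, ms_level=scan.ms_level)
            parent.children.append(node)
        node.add_scan(scan)
    return roots


def _find_node(nodes, mz: float, tol: float) -> MsnTreeNode | None:
    best = None
    best_d = tol
    for n in nodes:
        d = abs(n.node_precursor_mz - mz)
        if d <= best_d:
            best, best_d = n, d
    return best


def select_best_scan(node: MsnTreeNode, energy: float) -> ScanRecord | None:
    """Member scan at ``energy`` with maximal TIC; ties go to the earlier
    scan number. None if the node has no scan at that energy."""
    candidates = [s for s in node.member_scans if s.collision_energy == energy]
    if not candidates:
        return None
    return max(candidates, key=lambda s: (s.tic, -s.scan_number))


def format_tree(node: MsnTreeNode, indent: int = 0) -> str:
    """Indented text rendering of a tree for manual inspection."""
    flag = " [orphan]" if node.orphan else ""
    line = (
        f"{'  ' * indent}MS{node.ms_level} m/z {node.node_precursor_mz:.4f} "
        f"({len(node.member_scans)} scans, energies {node.energies()}){flag}"
    )
    return "\n".join([line] + [format_tree(c, indent + 1) for c in node.children])
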