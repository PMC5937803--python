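"""Curated mEPN models of steroidogenesis.

Two models are provided programmatically:

* :func:`build_human_framework` — a framework diagram of the canonical human
  steroidogenic pathways (cholesterol through progestogens, corticosteroids,
  mineralocorticoids, androgens and estrogens), with a gene node and a protein
  node per enzyme isoform and tissue tags for the adrenal zones, testis,
  ovary, prostate and placenta.  Reaction chemistry follows the standard
  endocrinology reviews; each reaction carries its citation string so the
  diagram keeps its role as a visual bibliography.

* :func:`build_rat_leydig` — a cell-specific androgen-pathway model of the
  rat Leydig cell, with a single protein node per enzyme (no gene nodes) and
  a token input on every enzyme and on the cholesterol supply.  This is the
  model that is parameterised with stage-resolved enzyme activities
  (progenitor / immature / adult) and executed as a stochastic Petri net.

Enzyme symbols are uppercase for human isoforms (CYP11A1, HSD17B3, ...) and
aggregate, isoform-free symbols for the rodent cell model (HSD17B, SRD5A,
AKR1C, ...).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .mepn import MepnGraph, NodeKind
from .schedule import InjectionSchedule, Segment, format_schedule

__all__ = [
    "Reaction",
    "ReactionTable",
    "StageActivityTable",
    "STAGES",
    "STAGE_WINDOWS",
    "LEYDIG_ENZYMES",
    "build_human_framework",
    "build_rat_leydig",
    "parameterize_leydig",
    "schedules_from_graph",
    "apply_schedules",
]

#: Leydig maturation stages and the time-block windows they occupy
STAGES = ("progenitor", "immature", "adult")
STAGE_WINDOWS: dict[str, tuple[int, int]] = {
    "progenitor": (1, 20),
    "immature": (21, 50),
    "adult": (51, 100),
}

LEYDIG_ENZYMES = ("CYP11A1", "HSD3B", "CYP17A1", "HSD17B", "SRD5A", "AKR1C")

_MILLER_AUCHUS = "Miller & Auchus 2011, Endocr Rev 32:81-151"


@dataclass(frozen=True)
class Reaction:
    substrate: str
    product: str
    enzyme: str
    tissues: frozenset[str] = frozenset()
    reference: str = ""

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValueError(f"substrate equals product: {self.substrate!r}")
        object.__setattr__(self, "tissues", frozenset(self.tissues))


@dataclass
class ReactionTable:
    """Declarative substrate/enzyme/product/tissue rows for one model."""

    name: str
    species: str
    reactions: list[Reaction] = field(default_factory=list)

    def steroids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.substrate)
            seen.setdefault(r.product)
        return list(seen)

    def enzymes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.enzyme)
        return list(seen)

    def steroid_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for r in self.reactions:
            g.add_edge(r.substrate, r.product)
        return g

    def check_connected_from(self, root: str = "cholesterol") -> None:
        g = self.steroid_digraph()
        if root not in g:
            raise ValueError(f"root steroid {root!r} absent from table")
        reachable = nx.descendants(g, root) | {root}
        orphans = set(g.nodes) - reachable
        if orphans:
            raise ValueError(
                f"steroids unreachable from {root!r}: {sorted(orphans)}"
            )

    # -- delimited text I/O ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substrate": [r.substrate for r in self.reactions],
                "enzyme": [r.enzyme for r in self.reactions],
                "product": [r.product for r in self.reactions],
                "tissues": [";".join(sorted(r.tissues)) for r in self.reactions],
                "reference": [r.reference for r in self.reactions],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, name: str = "", species: str = "") -> "ReactionTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        reactions = [
            Reaction(
                row["substrate"],
                row["product"],
                row["enzyme"],
                frozenset(t for t in str(row.get("tissues", "")).split(";") if t),
                str(row.get("reference", "")),
            )
            for _, row in df.iterrows()
        ]
        return cls(name or Path(path).stem, species, reactions)


# ---------------------------------------------------------------------------
# Stage-resolved enzyme activities


@dataclass
class StageActivityTable:
    """Enzyme × stage activities in pmol/minute/million cells."""

    df: pd.DataFrame  # index: enzyme symbol; columns: STAGES

    def __post_init__(self) -> None:
        df = self.df.astype(float)
        missing = [s for s in STAGES if s not in df.columns]
        if missing:
            raise ValueError(f"activity table missing stage columns: {missing}")
        df = df[list(STAGES)]
        if not (df.to_numpy() >= 0).all():
            raise ValueError("activities must be non-negative")
        if not pd.notna(df.to_numpy()).all():
            raise ValueError("activities must be finite")
        self.df = df

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence[float]]) -> "StageActivityTable":
        """Build from ``{enzyme: (progenitor, immature, adult)}``."""
        return cls(pd.DataFrame.from_dict(data, orient="index", columns=list(STAGES)))

    @property
    def enzymes(self) -> list[str]:
        return list(self.df.index)

    def activity(self, enzyme: str, stage: str) -> float:
        return float(self.df.loc[enzyme, stage])

    def max_activity(self) -> float:
        return float(self.df.to_numpy().max())

    def save(self, path: str | Path) -> None:
        self.df.rename_axis("enzyme").to_csv(path, sep="\t")

    @classmethod
    def load(cls, path: str | Path) -> "StageActivityTable":
        return cls(pd.read_csv(path, sep="\t", index_col="enzyme"))


# ---------------------------------------------------------------------------
# Graph construction helpers

_ADRENALS = ("adrenal reticularis", "adrenal glomerulosa", "adrenal fasciculata")
ALL_TISSUES = _ADRENALS + ("testis", "ovary", "prostate", "placenta")


def _chemspider_url(steroid: str) -> str:
    return "https://www.chemspider.com/Search.aspx?q=" + steroid.replace(" ", "+")


def _ensembl_url(gene: str) -> str:
    return "https://www.ensembl.org/Multi/Search/Results?q=" + gene


def _slug(name: str) -> str:
    return (
        name.lower()
        .replace(" ", "_")
        .replace("-", "_")
        .replace("α", "a")
        .replace("β", "b")
    )


def _graph_from_reactions(
    table: ReactionTable,
    *,
    gene_nodes: bool,
    shared_enzymes: bool,
    substrate_inputs: Sequence[str] = ("cholesterol",),
) -> MepnGraph:
    """Expand a reaction table into an mEPN graph.

    Every steroid becomes a biochemical node, every reaction a process node
    fed by its substrate and its enzyme's protein node.  With
    ``shared_enzymes`` one protein node serves all of an enzyme's reactions
    (the cell-specific convention); otherwise the enzyme is duplicated per
    reaction site with a shared label, and a single gene node per isoform
    links to every copy.  Each protein node and each listed substrate gets a
    token-input node.
    """
    graph = MepnGraph(name=table.name)

    for steroid in table.steroids():
        graph.add_node(
            _slug(steroid),
            NodeKind.BIOCHEMICAL,
            label=steroid,
            url=_chemspider_url(steroid),
        )

    gene_ids: dict[str, str] = {}
    if gene_nodes:
        for enzyme in table.enzymes():
            gid = f"gene_{enzyme}"
            graph.add_node(gid, NodeKind.GENE, label=enzyme, url=_ensembl_url(enzyme))
            gene_ids[enzyme] = gid

    shared_protein: dict[str, str] = {}
    token_inputs: dict[str, str] = {}

    def ensure_protein(enzyme: str, site: int) -> str:
        if shared_enzymes:
            if enzyme in shared_protein:
                return shared_protein[enzyme]
            pid = enzyme
        else:
            pid = f"{enzyme}@{site}"
        graph.add_node(pid, NodeKind.PROTEIN, label=enzyme)
        tid = f"TI_{pid}"
        graph.add_node(tid, NodeKind.TOKEN_INPUT, label=f"token input: {enzyme}")
        graph.add_edge(tid, pid)
        token_inputs[pid] = tid
        if shared_enzymes:
            shared_protein[enzyme] = pid
        if enzyme in gene_ids:
            graph.add_edge(gene_ids[enzyme], pid)
        return pid

    for i, rxn in enumerate(table.reactions):
        substrate, product = _slug(rxn.substrate), _slug(rxn.product)
        protein = ensure_protein(rxn.enzyme, i)
        process = f"rxn{i}_{substrate}_to_{product}"
        graph.add_node(
            process,
            NodeKind.PROCESS,
            label=f"{rxn.substrate} -> {rxn.product} ({rxn.enzyme})"
            + (f" [{rxn.reference}]" if rxn.reference else ""),
        )
        graph.add_edge(substrate, process)
        graph.add_edge(protein, process)
        graph.add_edge(process, product)
        for nid in (substrate, protein, process, product):
            if rxn.tissues:
                graph.tag_tissue(nid, *rxn.tissues)

    for substrate in substrate_inputs:
        sid = _slug(substrate)
        tid = f"TI_{sid}"
        graph.add_node(tid, NodeKind.TOKEN_INPUT, label=f"token input: {substrate}")
        graph.add_edge(tid, sid)

    return graph


# ---------------------------------------------------------------------------
# The human framework model


def human_framework_reactions() -> ReactionTable:
    """Canonical human steroidogenesis reactions with tissue assignments."""
    R = Reaction
    steroidogenic = frozenset(_ADRENALS + ("testis", "ovary", "placenta"))
    delta5 = frozenset(("adrenal reticularis", "testis", "ovary"))
    reactions = [
        R("cholesterol", "pregnenolone", "CYP11A1", steroidogenic, _MILLER_AUCHUS),
        R("pregnenolone", "17OH-pregnenolone", "CYP17A1", delta5, _MILLER_AUCHUS),
        R("17OH-pregnenolone", "DHEA", "CYP17A1", delta5, _MILLER_AUCHUS),
        R("pregnenolone", "progesterone", "HSD3B2", steroidogenic, _MILLER_AUCHUS),
        R("17OH-pregnenolone", "17OH-progesterone", "HSD3B2",
          frozenset(("adrenal fasciculata", "testis", "ovary")), _MILLER_AUCHUS),
        R("DHEA", "androstenedione", "HSD3B2", delta5, _MILLER_AUCHUS),
        R("progesterone", "17OH-progesterone", "CYP17A1",
          frozenset(("adrenal fasciculata", "testis", "ovary")), _MILLER_AUCHUS),
        R("progesterone", "11-deoxycorticosterone", "CYP21A2",
          frozenset(("adrenal glomerulosa",)), _MILLER_AUCHUS),
        R("11-deoxycorticosterone", "corticosterone", "CYP11B1",
          frozenset(("adrenal glomerulosa",)), _MILLER_AUCHUS),
        R("corticosterone", "aldosterone", "CYP11B2",
          frozenset(("adrenal glomerulosa",)), _MILLER_AUCHUS),
        R("17OH-progesterone", "11-deoxycortisol", "CYP21A2",
          frozenset(("adrenal fasciculata",)), _MILLER_AUCHUS),
        R("11-deoxycortisol", "cortisol", "CYP11B1",
          frozenset(("adrenal fasciculata",)), _MILLER_AUCHUS),
        R("androstenedione", "testosterone", "HSD17B3",
          frozenset(("testis",)), _MILLER_AUCHUS),
        R("androstenedione", "estrone", "CYP19A1",
          frozenset(("ovary", "placenta")), _MILLER_AUCHUS),
        R("testosterone", "estradiol", "CYP19A1",
          frozenset(("ovary", "placenta")), _MILLER_AUCHUS),
        R("estrone", "estradiol", "HSD17B1",
          frozenset(("ovary", "placenta")), _MILLER_AUCHUS),
        R("testosterone", "DHT", "SRD5A2",
          frozenset(("prostate", "testis")), _MILLER_AUCHUS),
    ]
    return ReactionTable("human-framework", "human", reactions)


#: representatives of the five steroid hormone classes in the framework
STEROID_CLASS_REPRESENTATIVES = {
    "progestogens": "progesterone",
    "corticosteroids": "cortisol",
    "mineralocorticoids": "aldosterone",
    "androgens": "testosterone",
    "estrogens": "estradiol",
}


def build_human_framework() -> MepnGraph:
    """The framework model of human steroidogenesis.

    Gene and protein nodes per enzyme isoform (proteins duplicated per
    reaction site, as the diagrams draw them); Chemspider URL on every
    steroid node and an Ensembl URL on every gene node; tissue tags covering
    the adrenal zones, testis, ovary, prostate and placenta.
    """
    table = human_framework_reactions()
    table.check_connected_from("cholesterol")
    return _graph_from_reactions(table, gene_nodes=True, shared_enzymes=False)


# ---------------------------------------------------------------------------
# The rat Leydig cell model


def rat_leydig_reactions() -> ReactionTable:
    """Androgen-pathway reactions of the rat Leydig cell (Δ4 route plus the
    5α-reduced androstanedione route; 3α-diol is the terminal metabolite)."""
    R = Reaction
    t = frozenset(("testis",))
    reactions = [
        R("cholesterol", "pregnenolone", "CYP11A1", t, _MILLER_AUCHUS),
        R("pregnenolone", "progesterone", "HSD3B", t, _MILLER_AUCHUS),
        R("progesterone", "17OH-progesterone", "CYP17A1", t, _MILLER_AUCHUS),
        R("17OH-progesterone", "androstenedione", "CYP17A1", t, _MILLER_AUCHUS),
        R("androstenedione", "testosterone", "HSD17B", t, _MILLER_AUCHUS),
        R("androstenedione", "androstanedione", "SRD5A", t, _MILLER_AUCHUS),
        R("androstanedione", "DHT", "HSD17B", t, _MILLER_AUCHUS),
        R("testosterone", "DHT", "SRD5A", t, _MILLER_AUCHUS),
        R("DHT", "3α-diol", "AKR1C", t, _MILLER_AUCHUS),
    ]
    return ReactionTable("rat-leydig", "rat", reactions)


def build_rat_leydig() -> MepnGraph:
    """The cell-specific rat Leydig androgen model.

    A single protein node represents all isoforms of each enzyme (so no gene
    nodes and no Ensembl links); every enzyme node and the cholesterol source
    carries a token input for parameterisation.
    """
    table = rat_leydig_reactions()
    table.check_connected_from("cholesterol")
    return _graph_from_reactions(table, gene_nodes=False, shared_enzymes=True)


def parameterize_leydig(
    graph: MepnGraph,
    activities: StageActivityTable,
    cholesterol_supply: float | None = None,
) -> dict[str, InjectionSchedule]:
    """Attach stage-block schedules to every enzyme node and the cholesterol
    supply.

    Each enzyme node receives ``1-20,p;21-50,i;51-100,a`` from its activity
    row; the cholesterol token input receives a constant ``1-100,s`` with
    ``s = cholesterol_supply`` (default: twice the largest activity in the
    table, so that enzymes — not substrate — are rate-limiting).  Schedules
    are returned keyed by target node id and are also written onto the
    token-input edge labels so a GraphML export carries the parameterisation.

    Raises ``KeyError`` naming any enzyme node absent from the table.
    """
    proteins = graph.nodes_of_kind(NodeKind.PROTEIN)
    schedules: dict[str, InjectionSchedule] = {}
    for node in proteins:
        symbol = node.label or node.id
        if symbol not in activities.df.index:
            raise KeyError(f"enzyme {symbol!r} missing from activity table")
        segments = tuple(
            Segment(STAGE_WINDOWS[stage][0], STAGE_WINDOWS[stage][1],
                    activities.activity(symbol, stage))
            for stage in STAGES
        )
        schedules[node.id] = InjectionSchedule(segments, target=node.id)

    if cholesterol_supply is None:
        cholesterol_supply = 2.0 * activities.max_activity()
    total = (1, STAGE_WINDOWS["adult"][1])
    schedules["cholesterol"] = InjectionSchedule(
        (Segment(total[0], total[1], float(cholesterol_supply)),),
        target="cholesterol",
    )
    apply_schedules(graph, schedules)
    return schedules


def apply_schedules(
    graph: MepnGraph, schedules: Mapping[str, InjectionSchedule]
) -> None:
    """Write schedule notation onto the token-input edge labels of *graph*."""
    for edge in graph.edges:
        src = graph.nodes.get(edge.source)
        if src is not None and src.kind == NodeKind.TOKEN_INPUT:
            sched = schedules.get(edge.target)
            if sched is not None:
                edge.label = format_schedule(sched)


def schedules_from_graph(graph: MepnGraph) -> dict[str, InjectionSchedule]:
    """Recover schedules from token-input edge labels (inverse of
    :func:`apply_schedules`); unlabelled token inputs inject nothing."""
    from .schedule import parse_schedule

    schedules: dict[str, InjectionSchedule] = {}
    for edge in graph.edges:
        src = graph.nodes.get(edge.source)
        if src is not None and src.kind == NodeKind.TOKEN_INPUT and edge.label:
            schedules[edge.target] = parse_schedule(edge.label, target=edge.target)
    return schedules
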