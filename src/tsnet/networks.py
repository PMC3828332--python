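"""Assembly and serialization of transcription-and-splicing networks (TSNs).

A TSN is the bipartite regulatory graph of one co-expression group: the
group's target isoforms on one side, the LARS-selected TFs and SFs on the
other. An edge factor -> isoform exists only where the factor was selected
for the group AND its interaction strength on that isoform is positive; the
edge carries the strength as weight and the sign of the factor's regression
coefficient (negative coefficients are read as inhibition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .lars import FitResult
from .preprocess import CoexpressionGroup

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    factor: str
    factor_type: str        # TF or SF
    isoform: str
    gene: str
    coefficient: float
    strength: float

    @property
    def sign(self) -> str:
        return "-" if self.coefficient < 0 else "+"


@dataclass
class RegulatoryNetwork:
    group_id: int | str
    targets: list[str]                  # isoform ids
    genes: dict[str, str]               # isoform -> gene name
    factors: dict[str, str]             # factor -> type
    edges: list[Edge] = field(default_factory=list)
    adjusted_r2: float = float("nan")
    isolated_factors: list[str] = field(default_factory=list)

    def gene_list(self) -> list[str]:
        """Deduplicated genes of targets and factors (factor name used as its
        gene symbol), as mapped into gene-set collections."""
        names = [self.genes.get(t, t) for t in self.targets] + list(self.factors)
        return sorted(dict.fromkeys(names))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(group_id=str(self.group_id), adjusted_r2=float(self.adjusted_r2))
        for iso in self.targets:
            g.add_node(iso, kind="target", gene=self.genes.get(iso, iso))
        for fac, ftype in self.factors.items():
            g.add_node(fac, kind=ftype)
        for e in self.edges:
            g.add_edge(e.factor, e.isoform, weight=e.strength,
                       coefficient=e.coefficient, sign=e.sign)
        return g


def assemble_network(
    fit: FitResult,
    group: CoexpressionGroup,
    tf_strengths: pd.DataFrame,
    sf_strengths: pd.DataFrame,
    gene_names: dict[str, str],
) -> RegulatoryNetwork:
    """Build the TSN for one kept fit from the interaction strength matrices."""
    if not fit.kept:
        raise ValueError(f"group {group.group_id}: fit was not kept (ill-fitting model)")
    if fit.group_id != group.group_id:
        raise ValueError(
            f"fit is for group {fit.group_id}, not group {group.group_id}"
        )
    net = RegulatoryNetwork(
        group_id=group.group_id,
        targets=list(group.members),
        genes={m: gene_names.get(m, m) for m in group.members},
        factors={f: fit.factor_types[f] for f in fit.selected},
        adjusted_r2=fit.adjusted_r2,
    )
    for fac in fit.selected:
        mat = tf_strengths if fit.factor_types[fac] == "TF" else sf_strengths
        touched = False
        for iso in group.members:
            s = float(mat.loc[iso, fac]) if (iso in mat.index and fac in mat.columns) else 0.0
            if s > 0:
                touched = True
                net.edges.append(
                    Edge(fac, fit.factor_types[fac], iso, net.genes[iso],
                         fit.coefficients[fac], s)
                )
        if not touched:
            # cannot normally happen: zero-strength-everywhere columns are
            # pruned before the fit
            net.isolated_factors.append(fac)
            log.warning("assemble_network: selected factor %s has no positive "
                        "strength in group %s", fac, group.group_id)
    return net


def networks_table(networks: list[RegulatoryNetwork]) -> pd.DataFrame:
    rows = [
        {
            "group_id": n.group_id,
            "factor": e.factor,
            "factor_type": e.factor_type,
            "coefficient": e.coefficient,
            "isoform": e.isoform,
            "gene": e.gene,
            "strength": e.strength,
        }
        for n in networks
        for e in n.edges
    ]
    return pd.DataFrame(
        rows,
        columns=["group_id", "factor", "factor_type", "coefficient",
                 "isoform", "gene", "strength"],
    )


def write_networks(networks: list[RegulatoryNetwork], tsv_path, graphml_dir=None):
    networks_table(networks).to_csv(tsv_path, sep="\t", index=False,
                                    float_format="%.6g")
    if graphml_dir is not None:
        from pathlib import Path

        d = Path(graphml_dir)
        d.mkdir(parents=True, exist_ok=True)
        for n in networks:
            nx.write_graphml(n.to_networkx(), d / f"network_{n.group_id}.graphml")


def read_networks(tsv_path) -> list[RegulatoryNetwork]:
    """Parse networks.tsv back into RegulatoryNetwork objects (round-trip of
    node/edge multisets; adjusted R-squared lives in the run report)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"factor": str, "isoform": str, "gene": str})
    nets = []
    for gid, sub in df.groupby("group_id", sort=True):
        net = RegulatoryNetwork(
            group_id=gid,
            targets=sorted(sub["isoform"].unique()),
            genes=dict(zip(sub["isoform"], sub["gene"])),
            factors=dict(zip(sub["factor"], sub["factor_type"])),
        )
        net.edges = [
            Edge(r.factor, r.factor_type, r.isoform, r.gene,
                 float(r.coefficient), float(r.strength))
            for r in sub.itertuples()
        ]
        nets.append(net)
    return nets
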