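import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from netpharm import adme, cgfc, importance, network
from netpharm.synthetic import generate


@pytest.fixture(scope="session")
def bundle():
    """One synthetic bundle shared by the whole suite (seed 1)."""
    return generate(seed=1)


@pytest.fixture(scope="session")
def pipeline_state(bundle):
    """The bundle pushed through screen → network → importance → EIS."""
    kept, verdicts = adme.screen_components(bundle.components)
    kept_ids = {c.component_id for c in kept}
    ct = bundle.ct_edges[bundle.ct_edges["source"].isin(kept_ids)].reset_index(drop=True)
    ct_net = network.build_ct_network(kept, ct)
    ctpd = network.assemble_ctpd(ct_net, bundle.ppi_edges, bundle.pathogenic)
    tp = network.extract_tp(ctpd)
    table = importance.node_importance(tp, graph_id="tp")
    eis = importance.extract_eis(tp, table)
    tmap = cgfc.component_target_map(ct)
    return {
        "kept": kept,
        "verdicts": verdicts,
        "ct": ct,
        "ctpd": ctpd,
        "tp": tp,
        "importance": table,
        "eis": eis,
        "tmap": tmap,
    }


@pytest.fixture
def toy_tp_graph():
    """Targets {A,B}, pathogenic {B,C}, PPI A-B, B-C."""
    g = nx.Graph()
    g.add_node("A", roles={"target"})
    g.add_node("B", roles={"target", "pathogenic"}, nv=3)
    g.add_node("C", roles={"pathogenic"}, nv=1)
    g.add_edge("A", "B", etype="PPI")
    g.add_edge("B", "C", etype="PPI")
    return g
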