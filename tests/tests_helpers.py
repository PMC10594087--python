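"""Small shared builders for tests."""
import numpy as np

from ordnet.datatypes import symmetric_network


def make_single_edge_networks(w1: float, w2: float):
    labels = ["a", "b"]
    m1 = np.array([[0.0, w1], [w1, 0.0]])
    m2 = np.array([[0.0, w2], [w2, 0.0]])
    return symmetric_network(m1, labels), symmetric_network(m2, labels)
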