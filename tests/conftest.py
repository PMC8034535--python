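import numpy as np
import pytest

from mendelprior.ontology import parse_obo

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: T:A
name: root A

[Term]
id: T:B
name: level B
is_a: T:A

[Term]
id: T:C
name: leaf C
is_a: T:B

[Term]
id: T:OBS
name: retired
is_a: T:A
is_obsolete: true
"""


@pytest.fixture
def chain_ontology():
    """A -> B -> C chain plus one obsolete child of the root."""
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dag_obo(rng, n_terms=30, extra_parent_p=0.3):
    """Random rooted is_a DAG as OBO text, parents drawn among earlier terms."""
    lines = ["format-version: 1.2", "", "[Term]", "id: R:0", "name: root", ""]
    ids = ["R:0"]
    for i in range(1, n_terms + 1):
        tid = f"R:{i}"
        lines += ["[Term]", f"id: {tid}", f"name: term {i}"]
        p1 = ids[int(rng.integers(0, len(ids)))]
        lines.append(f"is_a: {p1}")
        if len(ids) > 1 and rng.random() < extra_parent_p:
            p2 = ids[int(rng.integers(0, len(ids)))]
            if p2 != p1:
                lines.append(f"is_a: {p2}")
        lines.append("")
        ids.append(tid)
    return "\n".join(lines), ids
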