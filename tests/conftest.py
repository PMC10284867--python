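"""Shared fixtures: compiled records for every architecture and experiment type."""

from __future__ import annotations

import pytest

from cmdl import fixtures as fx
from cmdl.interpreter import compile_text

ARCHITECTURE_KINDS = (
    "homopolymer",
    "diol_telechelic",
    "graft",
    "dendrimer",
    "block_copolymer",
    "statistical_copolymer",
)

ALL_KINDS = ARCHITECTURE_KINDS + ("batch_rop", "flow_rop")


@pytest.fixture(scope="session")
def corpus():
    """kind -> (text, ExperimentRecord) for every fixture kind."""
    out = {}
    for kind in ALL_KINDS:
        text = fx.make_record(fx.FixtureSpec(kind=kind))
        record, diags = compile_text(text)
        assert record is not None, f"{kind} fixture failed to compile: {diags}"
        out[kind] = (text, record)
    return out


@pytest.fixture(scope="session")
def corpus_graphs(corpus):
    """All weighted polymer graphs from the fixture corpus."""
    graphs = []
    for _, record in corpus.values():
        graphs.extend(record.polymers.values())
    return graphs
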