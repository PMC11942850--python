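import json
from pathlib import Path

import pytest
from hypothesis import settings

from symbiopart import (
    CountMatrix, classify_all, filter_low_expression, parse_hits,
    tmm_normalize,
)
from symbiopart.syndata import SimConfig, generate_taxonomy, \
    write_fixture_bundle

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, sim_config):
    """A written fixture bundle plus its parsed objects and truth."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(sim_config, outdir)
    truth = json.loads(Path(paths["truth"]).read_text())
    tax = generate_taxonomy(sim_config)
    cm = CountMatrix.from_tsv(paths["counts"], paths["castes"])
    hits = parse_hits(paths["hits"])
    calls = classify_all(hits, tax, all_transcripts=list(cm.counts.index))
    return {"paths": paths, "truth": truth, "tax": tax, "cm": cm,
            "hits": hits, "calls": calls, "config": sim_config}


@pytest.fixture(scope="session")
def normalized(bundle):
    """Filtered counts, TMM factors and TMM matrix for the bundle."""
    filtered = filter_low_expression(bundle["cm"])
    factors, tmm = tmm_normalize(filtered)
    return {"filtered": filtered, "factors": factors, "tmm": tmm}
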