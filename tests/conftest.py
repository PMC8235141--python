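import pytest

from rna2dbarcode.energy import load_default_model
from rna2dbarcode.fold import fold_mfe
from rna2dbarcode.stemloops import (
    delimit_v_domain,
    load_reference_template,
    template_anchors,
)
from rna2dbarcode.synth import example_clade_spec, synthesize_clade


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def reference():
    return load_reference_template()


@pytest.fixture(scope="session")
def anchors():
    return template_anchors()


@pytest.fixture(scope="session")
def template_stemloops():
    """Stem-loops read off the known template architecture (no refolding).

    Valid whenever the generator leaves the template structure intact — the
    zero-background study conditions and pair-preserving background mutations
    both guarantee it; the folding route itself is covered separately.
    """
    from dataclasses import replace

    from rna2dbarcode.fold import PairTable, SecondaryStructure
    from rna2dbarcode.stemloops import extract_stemloops

    ref = load_reference_template()
    pt = PairTable.from_dotbracket(ref.source.dotbracket)

    def build(records, label="L7"):
        target = ref.by_label()[label]
        out = {}
        for rec in records:
            st = SecondaryStructure(rec, pt, 0.0)
            match = [
                sl for sl in extract_stemloops(st) if sl.closing_pair == target.closing_pair
            ]
            out[rec.id] = replace(match[0], label=label)
        return out

    return build


@pytest.fixture(scope="session")
def clade_cbc(model, reference, anchors):
    """One folded two-genus clade with a CBC planted in L8 (shared across tests).

    Folding a dozen V-domain sequences is the expensive step of the pipeline,
    so the realisation is computed once per session.
    """
    spec = example_clade_spec(seed=7, planted_cbc="CBC")
    records, truth = synthesize_clade(spec)
    v_domains = {
        rec.id: delimit_v_domain(fold_mfe(rec, model), anchors=anchors, reference=reference)
        for rec in records
    }
    return records, truth, v_domains
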