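"""Forward (product-prediction) model adapters for round-trip scoring.

Round-trip evaluation needs a product-prediction model matched to the
reactant-prediction model under test. Two adapters satisfy the
:data:`~rxnbench.metrics.ForwardModel` contract:

* :class:`TemplateOracleForward` — applies each record's generating
  template to the predicted reactants. It regenerates the true product for
  *any* reactant set the template maps there, which is exactly the property
  that makes round-trip scoring accept alternative precursor sets that
  strict top-1 matching rejects.
* :class:`TranslatorForward` — wraps a trained translator (same
  augmentation factor and reagent setting as the reactant model, by
  construction of the caller).
"""

from __future__ import annotations

from typing import Optional, Sequence

from .errors import RxnBenchError
from .metrics import PredictionRecord
from .molformat import canonicalize, split_molecules
from .synthetic import ReactionTemplate
from .tokenization import Tokenizer
from .transformer import Seq2SeqTranslator


class TemplateOracleForward:
    """Applies the generating template of each record to predicted reactants.

    The mapping is by ``record_id`` -> template. When the record's reagent
    setting is on, the true reagents appended to the forward input are
    removed again by exact multiset removal from the right (they are
    appended after the predicted reactants), mirroring a forward model that
    has learned reagents carry no atoms into the product.
    """

    def __init__(self, templates_by_record: dict[str, ReactionTemplate],
                 reagent_lists: dict[str, tuple[str, ...]] | None = None):
        self.templates_by_record = templates_by_record
        self.reagent_lists = reagent_lists or {}

    def __call__(self, sources: Sequence[str],
                 records: Sequence[PredictionRecord]) -> list[Optional[str]]:
        out: list[Optional[str]] = []
        for src, rec in zip(sources, records):
            rid = rec.record_id
            template = self.templates_by_record.get(rid)
            if template is None or not src:
                out.append(None)
                continue
            reactants = split_molecules(src)
            if rec.include_reagents:
                for reagent in self.reagent_lists.get(rid, ()):
                    for i in range(len(reactants) - 1, -1, -1):
                        if reactants[i] == reagent:
                            del reactants[i]
                            break
            try:
                # the template consumes the reactant *set*: duplicate
                # predictions collapse, mirroring set-based strict scoring
                unique = sorted({canonicalize(m) for m in reactants})
                out.append(template.transform(unique))
            except (RxnBenchError, ValueError):
                out.append(None)
        return out


class TranslatorForward:
    """A trained product-prediction translator as a forward model."""

    def __init__(self, model: Seq2SeqTranslator, tokenizer: Tokenizer,
                 batch_size: int = 16):
        self.model = model
        self.tokenizer = tokenizer
        self.batch_size = batch_size

    def __call__(self, sources: Sequence[str],
                 records: Sequence[PredictionRecord]) -> list[Optional[str]]:
        token_sources = []
        ok = []
        for src in sources:
            try:
                token_sources.append(self.tokenizer.tokenize(src))
                ok.append(True)
            except RxnBenchError:
                token_sources.append([])
                ok.append(False)
        preds = self.model.predict_strings(token_sources, k=1,
                                           batch_size=self.batch_size)
        return [p[0][0] if valid and p else None
                for p, valid in zip(preds, ok)]
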