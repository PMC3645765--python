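"""One-call orchestration of the full synthetic experiment.

Glue over the stage modules: simulate two libraries, process them into
high-quality tags, classify, call differential expression, and score the
result against the simulation truth. Mainly used for end-to-end validation
and reporting; each stage remains available separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import annotate as ann
from . import diffexpr as de
from . import readproc as rp
from . import simdata as sd

__all__ = ["ExperimentResult", "run_synthetic_experiment"]


@dataclass
class ExperimentResult:
    config: sd.SimConfig
    bundle: sd.ReferenceBundle
    truth: sd.TruthTable
    tags: rp.Tags
    filter_report: rp.FilterReport
    classification: ann.ClassificationResult
    de_results: list[de.DEResult]
    sensitivity: float
    false_positive_rate: float
    confusion_offdiagonal: float

    @property
    def de_called(self) -> int:
        return sum(r.de_flag for r in self.de_results)


def run_synthetic_experiment(
    config: sd.SimConfig,
    de_params: de.DEParams | None = None,
    annotate_params: ann.AnnotateParams | None = None,
) -> ExperimentResult:
    """Simulate, filter, classify and test one two-library experiment."""
    de_params = de_params or de.DEParams(abundance_min=0)
    bundle = sd.generate_references(config)
    reads_a, reads_b, truth = sd.simulate_libraries(bundle, config)
    filter_params = rp.FilterParams(adapter=config.adapter_sequence)
    tags, report = rp.process_pair(
        [r.sequence for r in reads_a],
        [r.sequence for r in reads_b],
        filter_params,
        bundle.contaminants,
    )
    classification = ann.classify_tags(tags, bundle, annotate_params)
    pairs = de.count_pairs_from_records(classification.unique_records)
    results = de.call_differential(pairs, de_params)

    called = {r.name: r.direction for r in results if r.de_flag}
    seqs = {r.name: r.reference_sequence for r in classification.unique_records}
    sens, fpr = sd.de_performance(called, bundle, config, truth, seqs)
    confusion = sd.classification_confusion(
        classification.assignments, bundle, config,
        {s: (t.count_a, t.count_b) for s, t in tags.items()},
    )
    return ExperimentResult(
        config=config, bundle=bundle, truth=truth, tags=tags, filter_report=report,
        classification=classification, de_results=results,
        sensitivity=sens, false_positive_rate=fpr,
        confusion_offdiagonal=sd.offdiagonal_rate(confusion),
    )
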