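"""End-to-end overlap-correction workflow.

The canonical experiment trains a classifier on one dataset's labeled
overlaps and uses it to correct a second, independent dataset before
assembly — the train-on-one-organism, assemble-another design.  At desk
scale both datasets are synthetic: two independently simulated repeat-rich
genomes, each with its own read set, ground-truth placements, and a small
panel of related genomes for the comparative feature.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from .assembly import (AssemblyReport, build_contigs, build_graph,
                       evaluate_assembly, filter_overlaps)
from .classify import ClassificationMetrics, OverlapClassifier
from .comp_features import (DEFAULT_TOLERANCE, GenomeIndex, comparative_evidence,
                            map_read_to_genome)
from .ground_truth import label_overlaps
from .io_formats import OverlapCandidate, SequenceRecord
from .noncomp_features import (DEFAULT_FEATURE_K, build_kmer_model,
                               compute_noncomp_features)
from .overlapper import (DEFAULT_MAX_ERROR, DEFAULT_MIN_OVERLAP, DEFAULT_SEED_K,
                         find_overlap_candidates)
from .simulate import (SimConfig, TruePlacement, derive_related_genome,
                       simulate_genome, simulate_reads)

logger = logging.getLogger(__name__)

COMP_FEATURE = "comp_score"


@dataclass
class Dataset:
    """One simulated sequencing experiment."""

    name: str
    genome: SequenceRecord
    reads: list[SequenceRecord]
    placements: list[TruePlacement]
    panel: list[SequenceRecord] = field(default_factory=list)
    panel_identities: list[float] = field(default_factory=list)
    coverage: float = 10.0

    @property
    def reads_by_id(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.reads}


@dataclass
class Benchmark:
    train: Dataset
    test: Dataset
    config: SimConfig
    seed: int


def make_benchmark(seed: int, config: SimConfig | None = None) -> Benchmark:
    """Two independently simulated datasets sharing no sequence, each with a
    panel of related genomes per the configured divergences."""
    if config is None:
        config = SimConfig()
    children = np.random.SeedSequence(seed).spawn(2)
    datasets = []
    for name, ss in zip(("train", "test"), children):
        rng = np.random.default_rng(ss)
        genome, _repeats = simulate_genome(config, rng, genome_id=f"{name}_genome")
        reads, placements = simulate_reads(genome, config, rng,
                                           id_prefix=f"{name[0]}")
        panel, idents = [], []
        for gi, div in enumerate(config.related_genomes):
            rel, ident = derive_related_genome(
                genome, div, rng, genome_id=f"{name}_rel{gi + 1}")
            panel.append(rel)
            idents.append(ident)
        datasets.append(Dataset(name, genome, reads, placements, panel, idents,
                                coverage=config.coverage))
        logger.info("benchmark %s: genome %d bp, %d reads, panel identities %s",
                    name, len(genome.seq), len(reads),
                    [f"{i:.3f}" for i in idents])
    return Benchmark(datasets[0], datasets[1], config, seed)


def extract_features(dataset: Dataset,
                     noncomparative: bool = True,
                     comparative: bool = True,
                     feature_k: int = DEFAULT_FEATURE_K,
                     seed_k: int = DEFAULT_SEED_K,
                     min_overlap: int = DEFAULT_MIN_OVERLAP,
                     max_error: float = DEFAULT_MAX_ERROR,
                     tolerance: int = DEFAULT_TOLERANCE,
                     ) -> tuple[list[OverlapCandidate], pd.DataFrame, np.ndarray]:
    """Overlap detection, feature extraction and ground-truth labeling.

    Returns (candidates, feature table, boolean labels); the feature table
    contains the key columns plus the enabled feature families.
    """
    if not (noncomparative or comparative):
        raise ValueError("at least one feature family must be enabled")
    t0 = time.perf_counter()
    candidates = find_overlap_candidates(dataset.reads, seed_k=seed_k,
                                         min_overlap=min_overlap,
                                         max_error=max_error)
    logger.info("%s: %d overlap candidates from %d reads (%.1fs)",
                dataset.name, len(candidates), len(dataset.reads),
                time.perf_counter() - t0)
    reads_by_id = dataset.reads_by_id

    if noncomparative:
        t0 = time.perf_counter()
        model = build_kmer_model(dataset.reads, k=feature_k,
                                 expected_coverage=dataset.coverage)
        features = compute_noncomp_features(candidates, reads_by_id, model)
        logger.info("%s: non-comparative features (%.1fs)", dataset.name,
                    time.perf_counter() - t0)
    else:
        features = pd.DataFrame(
            [(c.readA_id, c.readB_id, c.orientation) for c in candidates],
            columns=list(_classify.KEY_COLUMNS))

    if comparative:
        if not dataset.panel:
            raise ValueError(f"dataset {dataset.name} has no genome panel")
        t0 = time.perf_counter()
        hits = {}  # (read_id, genome_id) -> hits
        indices = [GenomeIndex(g) for g in dataset.panel]
        needed = sorted({rid for c in candidates
                         for rid in (c.readA_id, c.readB_id)})
        for rid in needed:
            for idx in indices:
                hits[(rid, idx.genome.id)] = map_read_to_genome(
                    reads_by_id[rid], idx)
        scores = []
        for c in candidates:
            ev = comparative_evidence(
                c,
                {g.id: hits[(c.readA_id, g.id)] for g in dataset.panel},
                {g.id: hits[(c.readB_id, g.id)] for g in dataset.panel},
                tolerance=tolerance)
            scores.append(np.nan if ev.score is None else ev.score)
        features[COMP_FEATURE] = scores
        logger.info("%s: comparative scores against %d genomes (%.1fs)",
                    dataset.name, len(dataset.panel), time.perf_counter() - t0)

    labels = np.array([l.label for l in
                       label_overlaps(candidates, dataset.placements,
                                      min_true_overlap=min_overlap)])
    logger.info("%s: ground truth %d true / %d false", dataset.name,
                int(labels.sum()), int((~labels).sum()))
    return candidates, features, labels


@dataclass
class PipelineResult:
    """Outputs of one train-and-correct experiment."""

    classifier: OverlapClassifier
    metrics: ClassificationMetrics
    uncorrected: AssemblyReport
    corrected: AssemblyReport
    n_candidates: int
    n_retained: int
    train_features: pd.DataFrame
    train_labels: np.ndarray
    test_features: pd.DataFrame
    test_labels: np.ndarray

    def summary(self) -> str:
        return (f"classification: {self.metrics.summary()}\n"
                f"uncorrected: {self.uncorrected.summary()}\n"
                f"corrected:   {self.corrected.summary()}\n"
                f"overlaps retained: {self.n_retained}/{self.n_candidates}")


def run_pipeline(train: Dataset, test: Dataset,
                 algorithm: str = "random_forest",
                 noncomparative: bool = True, comparative: bool = True,
                 seed: int = 0, **feature_kwargs) -> PipelineResult:
    """Train on one dataset, classify and correct the other, assemble both
    uncorrected (control) and corrected overlap sets, and evaluate."""
    _, train_feat, train_lab = extract_features(
        train, noncomparative, comparative, **feature_kwargs)
    classifier = _classify.train(train_feat, train_lab, algorithm, seed=seed)

    candidates, test_feat, test_lab = extract_features(
        test, noncomparative, comparative, **feature_kwargs)
    predicted = classifier.predict(test_feat)
    metrics = _classify.evaluate(predicted, test_lab)
    logger.info("test classification: %s", metrics.summary())

    retained = filter_overlaps(candidates, list(predicted))
    reports = {}
    for label, cands in (("uncorrected", candidates), ("corrected", retained)):
        t0 = time.perf_counter()
        graph = build_graph(test.reads, cands, require_confirmation=True)
        contigs = build_contigs(graph, test.reads)
        reports[label] = evaluate_assembly(contigs, test.genome)
        logger.info("%s assembly: %s (%.1fs)", label, reports[label].summary(),
                    time.perf_counter() - t0)
    return PipelineResult(classifier, metrics, reports["uncorrected"],
                          reports["corrected"], len(candidates), len(retained),
                          train_feat, train_lab, test_feat, test_lab)
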