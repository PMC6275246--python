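"""End-to-end orchestration: reads (or intensities) in, subtype calls out.

The full flow is: load target sequences -> drop AFFX controls -> build k-mer
index -> pseudoalign + EM per sample -> TPM matrix -> quantile-normalize test
columns to the training mean-intensity distribution -> ComBat over training
and test together -> train the centroid classifier on the adjusted training
data -> classify the adjusted test samples -> project everything into the
frozen training PC space. A microarray matrix can be substituted for the
sequencing input, in which case the identical normalize/correct/classify path
is applied to intensities — the property that makes the two platforms
directly comparable.

There is no command-line layer: ``PipelineConfig`` + ``run_rnabc`` *is* the
public entry point, driven from Python (see the examples directory).
``skip_normalize`` and ``skip_combat`` exist for component-ablation studies
and are applied to whichever input the run consumes, so paired runs stay
same-treatment on both platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .batch_correction import BatchDesign, CombatParameters, combat
from .classifier import (SubtypeCall, SubtypeModel, calls_to_frame,
                         classify_matrix, train_subtype_model)
from .matrix import ExpressionMatrix, hstack
from .normalization import (quantile_normalize_to_target,
                            target_distribution_from_training)
from .probe_reference import (ProbeTargetSet, build_kmer_index,
                              load_target_fasta, remove_control_probesets)
from .projection import PcaModel, fit_pca, project_samples
from .pseudoalign import AbundanceTable, ReadSet, quantify

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Aggregated configuration or data error; message lists all violations."""


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Every input can be given either as a file path (FASTA/FASTQ/TSV) or as an
    in-memory object; objects win when both are set. Exactly one of the test
    inputs (``readsets``/``fastq`` or ``test_matrix``) must be provided.
    """

    # reference
    target_fasta: str | Path | None = None
    targets: ProbeTargetSet | None = None
    # training cohort
    training_tsv: str | Path | None = None
    training: ExpressionMatrix | None = None
    labels: list[str] | None = None
    labels_tsv: str | Path | None = None
    signature_ids: list[str] | None = None
    signature_tsv: str | Path | None = None
    # test input: sequencing ...
    fastq: dict[str, tuple[str | Path, ...]] | None = None
    readsets: dict[str, ReadSet] | None = None
    # ... or microarray
    test_matrix: ExpressionMatrix | None = None
    # parameters
    k: int = 31
    stranded: bool = False
    distance_method: str = "dlda"
    outlier_rule: str = "med_plus_n_mad"
    pca_scale: bool = True
    n_components: int = 2
    covariates: pd.DataFrame | None = None
    skip_normalize: bool = False
    skip_combat: bool = False
    out_dir: str | Path | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    calls: list[SubtypeCall]
    model: SubtypeModel
    abundances: dict[str, AbundanceTable] | None
    test_input: ExpressionMatrix
    normalized_test: ExpressionMatrix
    adjusted_training: ExpressionMatrix
    adjusted_test: ExpressionMatrix
    combat_params: CombatParameters | None
    pca: PcaModel
    train_scores: pd.DataFrame
    test_scores: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every configuration violation at once; empty list means valid."""
    errors: list[str] = []

    def _path_ok(p, what):
        if p is not None and not Path(p).exists():
            errors.append(f"{what} does not exist: {p}")

    if config.targets is None and config.target_fasta is None:
        errors.append("a target FASTA path or ProbeTargetSet is required")
    _path_ok(config.target_fasta if config.targets is None else None, "target FASTA")
    if config.training is None and config.training_tsv is None:
        errors.append("a training matrix (TSV path or ExpressionMatrix) is required")
    _path_ok(config.training_tsv if config.training is None else None, "training TSV")
    if config.labels is None and config.labels_tsv is None:
        errors.append("training subtype labels are required")
    _path_ok(config.labels_tsv if config.labels is None else None, "labels TSV")
    if config.signature_ids is None and config.signature_tsv is None:
        errors.append("a signature probe-set list is required")
    _path_ok(config.signature_tsv if config.signature_ids is None else None,
             "signature list")

    n_test_inputs = sum(
        x is not None for x in (config.fastq, config.readsets, config.test_matrix)
    )
    if n_test_inputs == 0:
        errors.append("a test input (FASTQ paths, ReadSets, or a matrix) is required")
    elif n_test_inputs > 1:
        errors.append("give exactly one test input kind (reads or matrix, not both)")
    if config.fastq is not None:
        for sample, paths in config.fastq.items():
            for p in paths:
                _path_ok(p, f"FASTQ for sample {sample!r}")

    if config.k % 2 == 0 or not (11 <= config.k <= 63):
        errors.append(f"k must be odd and in [11, 63], got {config.k}")
    if config.distance_method not in ("dlda", "pearson"):
        errors.append(f"unknown distance_method {config.distance_method!r}")
    if config.outlier_rule not in ("med_plus_n_mad", "n_mad"):
        errors.append(f"unknown outlier_rule {config.outlier_rule!r}")
    if config.n_components < 1:
        errors.append("n_components must be >= 1")
    return errors


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_labels(path: str | Path) -> list[str]:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise PipelineError("labels TSV needs sample_id and subtype columns")
    return [str(x) for x in frame.iloc[:, 1]]


def _load_signature(path: str | Path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def _resolve_inputs(config: PipelineConfig):
    targets = config.targets or load_target_fasta(config.target_fasta)
    training = config.training or ExpressionMatrix.read_tsv(
        config.training_tsv, "log2_intensity"
    )
    labels = config.labels if config.labels is not None else _load_labels(config.labels_tsv)
    signature = (
        config.signature_ids
        if config.signature_ids is not None
        else _load_signature(config.signature_tsv)
    )
    readsets = config.readsets
    if readsets is None and config.fastq is not None:
        readsets = {
            sample: ReadSet.from_fastq(*paths)
            for sample, paths in config.fastq.items()
        }
    return targets, training, labels, signature, readsets


def run_rnabc(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; see the module docstring for the stages."""
    errors = validate_config(config)
    if errors:
        raise PipelineError("invalid configuration:\n- " + "\n- ".join(errors))

    stage = "load inputs"
    try:
        targets, training, labels, signature, readsets = _resolve_inputs(config)

        stage = "remove control probe sets"
        noncontrol = remove_control_probesets(targets)

        abundances: dict[str, AbundanceTable] | None = None
        if readsets is not None:
            stage = "build k-mer index"
            index = build_kmer_index(noncontrol, k=config.k, stranded=config.stranded)
            stage = "pseudoalign and estimate abundance"
            abundances = {}
            cols = {}
            for sample, reads in readsets.items():
                table = quantify(reads, index)
                abundances[sample] = table
                cols[sample] = pd.Series(table.tpm, index=list(table.target_ids))
            test_input = ExpressionMatrix(pd.DataFrame(cols), "tpm")
        else:
            test_input = config.test_matrix

        stage = "align matrix rows"
        common = [r for r in training.row_ids if r in test_input.frame.index]
        if len(common) < len(training.row_ids):
            logger.info(
                "restricting to %d/%d probe sets shared by training and test",
                len(common), len(training.row_ids),
            )
        if not common:
            raise PipelineError("training and test matrices share no probe sets")
        training_m = training.subset_rows(common)
        test_m = test_input.subset_rows(common)

        if config.skip_normalize:
            normalized_test = test_m
        else:
            stage = "quantile normalization"
            target_dist = target_distribution_from_training(training_m)
            normalized_test = quantile_normalize_to_target(test_m, target_dist)

        combat_params: CombatParameters | None = None
        skip_combat = config.skip_combat
        if not skip_combat and test_m.shape[1] < 2:
            import warnings
            warnings.warn(
                "single test sample: batch correction needs >=2 samples per "
                "batch and is skipped; run samples in batches for reliable "
                "co-normalization", stacklevel=2,
            )
            skip_combat = True
        if skip_combat:
            adjusted_training, adjusted_test = training_m, normalized_test
        else:
            stage = "batch correction"
            pooled = hstack(
                training_m,
                ExpressionMatrix(normalized_test.frame, training_m.scale_tag),
                scale_tag="normalized",
            )
            batch = ["training"] * training_m.shape[1] + ["test"] * test_m.shape[1]
            design = BatchDesign(batch, config.covariates)
            adjusted, combat_params = combat(pooled, design)
            adjusted_training = adjusted.subset_cols(training_m.col_ids)
            adjusted_test = adjusted.subset_cols(test_m.col_ids)

        stage = "train classifier"
        model = train_subtype_model(
            adjusted_training, labels, signature,
            distance_method=config.distance_method,
            outlier_rule=config.outlier_rule,
        )
        stage = "classify test samples"
        calls = classify_matrix(adjusted_test, model)

        stage = "PCA projection"
        pca = fit_pca(adjusted_training.subset_rows(signature),
                      scale_features=config.pca_scale)
        train_scores = project_samples(adjusted_training, pca, config.n_components)
        test_scores = project_samples(adjusted_test, pca, config.n_components)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = _build_manifest(config)
    result = PipelineResult(
        calls=calls,
        model=model,
        abundances=abundances,
        test_input=test_input,
        normalized_test=normalized_test,
        adjusted_training=adjusted_training,
        adjusted_test=adjusted_test,
        combat_params=combat_params,
        pca=pca,
        train_scores=train_scores,
        test_scores=test_scores,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _build_manifest(config: PipelineConfig) -> dict:
    params = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if value is None or isinstance(value, (int, float, bool, str)):
            params[f.name] = value
        elif isinstance(value, Path):
            params[f.name] = str(value)
        else:
            params[f.name] = f"<in-memory {type(value).__name__}>"
    checksums = {}
    for name in ("target_fasta", "training_tsv", "labels_tsv", "signature_tsv"):
        p = getattr(config, name)
        if p is not None and Path(p).exists():
            checksums[name] = _sha256(p)
    if config.fastq:
        for sample, paths in config.fastq.items():
            for i, p in enumerate(paths):
                if Path(p).exists():
                    checksums[f"fastq:{sample}:{i}"] = _sha256(p)
    return {"package_version": _pkg_version, "parameters": params,
            "input_sha256": checksums}


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.calls_frame.to_csv(out_dir / "subtype_calls.tsv", sep="\t",
                              index=False, float_format="%.10g")
    result.normalized_test.write_tsv(out_dir / "normalized_test.tsv")
    result.adjusted_test.write_tsv(out_dir / "adjusted_test.tsv")
    result.adjusted_training.write_tsv(out_dir / "adjusted_training.tsv")
    result.model.to_json(out_dir / "subtype_model.json")
    result.train_scores.to_csv(out_dir / "train_pc_scores.tsv", sep="\t",
                               float_format="%.10g")
    result.test_scores.to_csv(out_dir / "test_pc_scores.tsv", sep="\t",
                              float_format="%.10g")
    if result.abundances:
        ab_dir = out_dir / "abundance"
        ab_dir.mkdir(exist_ok=True)
        for sample, table in result.abundances.items():
            table.write_tsv(ab_dir / f"{sample}.tsv")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
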