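"""End-to-end evaluation: a directory of predicted models against a config.

The external predictor (ColabFold / AF2) is integrated by file contract
only: its PDB outputs are dropped into a directory, optionally with a
``manifest.json`` recording per-model ``run_id`` values for run accounting.
``run_evaluation`` reads every model, computes dual-reference RMSDs and the
region's mean plDDT, classifies each model, and writes a per-model TSV plus
an ensemble JSON summary.  Outputs are byte-identical across re-runs on
identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .metrics import (
    ClassificationThresholds,
    ConformationCall,
    EnsembleSummary,
    ProteinTruth,
    classify_model,
    runs_accounting,
    summarize_ensemble,
)
from .msa import SubsampleSpec
from .structure import ReferencePair, dual_rmsd, mean_plddt, read_model

logger = logging.getLogger(__name__)

#: per-protein subsampling depths (max_extra_seq = 2 * max_seq throughout)
SUBSAMPLE_PRESETS = {"KaiB": 1, "Mad2": 8, "RfaH": 64}

_CONFIG_KEYS = {
    "protein", "msa", "ref_ground", "ref_alt", "region", "truth",
    "subsample", "thresholds", "atom_mode", "outdir",
}
_SUBSAMPLE_KEYS = {"max_seq", "max_extra_seq", "seed"}
_THRESHOLD_KEYS = {"accurate_rmsd", "accurate_plddt", "high_conf_plddt", "poor_rmsd"}


@dataclass
class RunConfig:
    protein: str
    ref_ground: Path
    ref_alt: Path
    region: tuple[int, int]
    truth: ProteinTruth
    thresholds: ClassificationThresholds
    subsample: SubsampleSpec | None = None
    msa: Path | None = None
    atom_mode: str = "all_heavy"
    outdir: Path = Path("results")

    def __post_init__(self) -> None:
        for p in (self.ref_ground, self.ref_alt):
            if not Path(p).exists():
                raise ValidationError(f"reference file not found: {p}")
        if self.msa is not None and not Path(self.msa).exists():
            raise ValidationError(f"MSA file not found: {self.msa}")


def default_subsample_spec(protein: str, seed: int = 0) -> SubsampleSpec:
    """Preset subsampling depth for a protein (max_seq 1/8/64 for
    KaiB/Mad2/RfaH), with max_extra_seq = 2 * max_seq."""
    if protein not in SUBSAMPLE_PRESETS:
        raise ValidationError(
            f"no preset for {protein!r}; known: {sorted(SUBSAMPLE_PRESETS)}"
        )
    return SubsampleSpec(max_seq=SUBSAMPLE_PRESETS[protein], seed=seed)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys are rejected (fail-fast)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("protein", "ref_ground", "ref_alt", "region", "truth"):
        if key not in raw:
            raise ValidationError(f"{path}: missing required key {key!r}")
    region = raw["region"]
    if not (isinstance(region, (list, tuple)) and len(region) == 2):
        raise ValidationError(f"{path}: region must be [start, end]")

    sub = None
    if "subsample" in raw:
        sub_raw = raw["subsample"] or {}
        unknown = set(sub_raw) - _SUBSAMPLE_KEYS
        if unknown:
            raise ValidationError(f"{path}: unknown subsample keys {sorted(unknown)}")
        sub = SubsampleSpec(**sub_raw)
    elif raw["protein"] in SUBSAMPLE_PRESETS:
        sub = default_subsample_spec(raw["protein"])

    th_raw = raw.get("thresholds") or {}
    unknown = set(th_raw) - _THRESHOLD_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown threshold keys {sorted(unknown)}")

    return RunConfig(
        protein=raw["protein"],
        ref_ground=Path(raw["ref_ground"]),
        ref_alt=Path(raw["ref_alt"]),
        region=(int(region[0]), int(region[1])),
        truth=ProteinTruth(observed=frozenset(raw["truth"])),
        thresholds=ClassificationThresholds(**th_raw),
        subsample=sub,
        msa=Path(raw["msa"]) if raw.get("msa") else None,
        atom_mode=raw.get("atom_mode", "all_heavy"),
        outdir=Path(raw.get("outdir", "results")),
    )


def load_references(config: RunConfig) -> ReferencePair:
    return ReferencePair(
        ground=read_model(config.ref_ground),
        alternative=read_model(config.ref_alt),
        region=config.region,
    )


def run_evaluation(
    config: RunConfig,
    models_dir: str | Path,
    method: str = "",
    write: bool = True,
) -> tuple[EnsembleSummary, pd.DataFrame]:
    """Evaluate every PDB model in a directory against the config's
    references; returns the ensemble summary and the per-model table.

    Unreadable models are logged and skipped; the run fails only if no
    model can be read.  When ``write`` is true, ``per_model.tsv`` and
    ``summary.json`` are written to ``config.outdir`` with fixed float
    formatting, so repeated runs are byte-identical.
    """
    models_dir = Path(models_dir)
    paths = sorted(models_dir.glob("*.pdb"))
    if not paths:
        raise ValidationError(f"no PDB models found in {models_dir}")
    refs = load_references(config)

    calls: list[ConformationCall] = []
    rows = []
    n_failed = 0
    for path in paths:
        try:
            model = read_model(path)
            dual = dual_rmsd(model, refs, atom_mode=config.atom_mode)
            plddt = mean_plddt(model, config.region)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            logger.warning("skipping %s: %s", path.name, exc)
            n_failed += 1
            continue
        call = classify_model(dual, plddt, config.thresholds, source=path.name)
        calls.append(call)
        rows.append({
            "model": path.name,
            "rmsd_ground": dual.rmsd_ground,
            "rmsd_alt": dual.rmsd_alt,
            "n_atoms": dual.n_atoms,
            "plddt": plddt,
            "label": call.label,
            "accurate": call.accurate,
            "high_confidence": call.high_confidence,
        })
        logger.info(
            "%s rmsd_ground=%.3f rmsd_alt=%.3f plddt=%.2f label=%s",
            path.name, dual.rmsd_ground, dual.rmsd_alt, plddt, call.label,
        )
    if not calls:
        raise ValidationError(f"all {n_failed} models in {models_dir} unreadable")

    manifest_path = models_dir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            runs = runs_accounting(json.load(fh).get("models", []))
    else:
        runs = len(calls)

    summary = summarize_ensemble(
        calls, config.truth, config.thresholds,
        runs=runs, protein=config.protein, method=method,
    )
    table = pd.DataFrame(rows)
    if write:
        config.outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(
            config.outdir / "per_model.tsv", sep="\t", index=False,
            float_format="%.4f",
        )
        with open(config.outdir / "summary.json", "w") as fh:
            json.dump(dataclasses.asdict(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary, table


def compare_methods(summaries: list[EnsembleSummary]) -> pd.DataFrame:
    """Side-by-side comparison of ensemble summaries from >= 2 methods.

    All methods must cover the same protein set; the table reports MCC,
    %success, per-model success rate, and runs per ensemble, plus the
    run-efficiency ratio of each method relative to the cheapest one.
    """
    if len(summaries) < 2:
        raise ValidationError("need at least two summaries to compare")
    by_method: dict[str, set[str]] = {}
    for s in summaries:
        by_method.setdefault(s.method or "method", set()).add(s.protein)
    protein_sets = list(by_method.values())
    if any(ps != protein_sets[0] for ps in protein_sets[1:]):
        raise ValidationError(
            f"mismatched protein sets across methods: "
            f"{ {m: sorted(p) for m, p in by_method.items()} }"
        )
    rows = [{
        "protein": s.protein,
        "method": s.method or "method",
        "mcc": s.mcc,
        "percent_success": s.percent_success,
        "success_rate": s.success_rate,
        "runs": s.runs,
    } for s in summaries]
    table = pd.DataFrame(rows).sort_values(["protein", "method"]).reset_index(drop=True)
    min_runs = table.groupby("protein")["runs"].transform("min")
    table["run_ratio"] = table["runs"] / min_runs
    return table
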