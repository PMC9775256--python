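"""Damage-simulation study driver.

Defines damage cases (named sets of missing landmarks), runs seeded
leave-target-out reconstruction simulations, and assembles accuracy
records with their inferential statistics.

For every randomly chosen target specimen the remaining specimens form the
reference sample: they are re-aligned (GPA) and re-slid without the
target, the RM regression is fitted on them, the target's raw
configuration is damaged according to the case, imputed, and two partial
Procrustes distances are recorded — d(true, predicted) and d(true,
reference consensus).  The second is the accuracy of using the mean shape
as the reconstruction template, the baseline the regression must beat.

The default cases follow the zygomatic damage scenarios: Case 1 =
landmarks {1, 2} (incomplete temporal process), Case 2 = {4, 5, 7}
(damaged orbit), Case 3 = semilandmarks {16..21} (incomplete body).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MorphorecError
from .imputation import DamagedConfiguration, fit_rm
from .io import SEMILANDMARK, LandmarkDataset
from .procrustes import GPAResult, gpa, procrustes_distance
from .sliding import slide_semilandmarks
from .stats import (
    AnovaResult,
    TTestResult,
    TukeyComparison,
    anova_with_tukey,
    paired_t,
    two_sample_t,
)

logger = logging.getLogger(__name__)

_MIN_EXTRA = 10  # documented floor: filtered subsample >= n_targets + 10


@dataclass(frozen=True)
class CaseDefinition:
    """A named damage scenario: the 1-based landmarks to delete."""

    name: str
    missing_indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(sorted(set(int(i) for i in self.missing_indices)))
        if not idx or idx[0] < 1:
            raise MorphorecError(
                f"case {self.name!r}: missing set must be non-empty, 1-based"
            )
        object.__setattr__(self, "missing_indices", idx)


#: The three zygomatic damage scenarios of the study design.
PAPER_CASES = (
    CaseDefinition("Case 1", (1, 2)),
    CaseDefinition("Case 2", (4, 5, 7)),
    CaseDefinition("Case 3", (16, 17, 18, 19, 20, 21)),
)


@dataclass(frozen=True)
class ReconstructionRecord:
    """Accuracy of one simulated reconstruction."""

    case_name: str
    target_id: str
    d_true_pred: float  # Procrustes distance true vs RM-completed
    d_true_mean: float  # Procrustes distance true vs reference consensus
    n_reference: int


def detect_outliers(gpa_result: GPAResult) -> pd.DataFrame:
    """Flag specimens whose distance to the consensus exceeds
    Q3 + 1.5 IQR.

    Returns every specimen's distance plus a boolean flag; review (and any
    exclusion) is a human step, nothing is dropped automatically.
    """
    if gpa_result.n < 4:
        raise MorphorecError(
            f"outlier screen needs n >= 4 specimens, got {gpa_result.n}"
        )
    d = np.linalg.norm(
        gpa_result.aligned - gpa_result.consensus, axis=(1, 2)
    )
    q1, q3 = np.percentile(d, [25, 75])
    cutoff = q3 + 1.5 * (q3 - q1)
    ids = gpa_result.specimen_ids or tuple(
        str(i) for i in range(gpa_result.n)
    )
    return pd.DataFrame(
        {
            "specimen_id": ids,
            "distance_to_consensus": d,
            "flagged": d > cutoff,
        }
    )


def _align_reference(
    reference: LandmarkDataset,
    slide: bool,
    sliding_iterations: int,
    gpa_tol: float,
) -> GPAResult:
    result = gpa(reference, tol=gpa_tol)
    if slide and SEMILANDMARK in reference.roles:
        result = slide_semilandmarks(
            result, iterations=sliding_iterations, gpa_tol=gpa_tol
        )
    return result


def run_case(
    dataset: LandmarkDataset,
    case: CaseDefinition,
    n_targets: int,
    seed,
    slide: bool = True,
    sliding_iterations: int = 3,
    gpa_tol: float = 1e-8,
    target_ids: Sequence[str] | None = None,
) -> list[ReconstructionRecord]:
    """Leave-target-out reconstruction simulation for one damage case.

    ``n_targets`` target specimens are sampled without replacement with the
    given seed (or supplied explicitly via ``target_ids``).  For each
    target the remaining specimens are re-aligned and re-slid from scratch
    (strict leave-one-out), the RM model is fitted, the target's raw
    configuration is damaged and imputed, and both accuracy distances are
    recorded.  A failing target aborts the run with its id attached.
    """
    if target_ids is None:
        if n_targets > len(dataset):
            raise MorphorecError(
                f"n_targets={n_targets} exceeds sample size {len(dataset)}"
            )
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(dataset), size=n_targets, replace=False)
        target_ids = [dataset[i].specimen_id for i in sorted(chosen)]
    records = []
    for target_id in target_ids:
        try:
            target = dataset.get(target_id)
            reference = dataset.drop(target_id)
            ref_aligned = _align_reference(
                reference, slide, sliding_iterations, gpa_tol
            )
            rm = fit_rm(ref_aligned, case.missing_indices)
            damaged = DamagedConfiguration(target, case.missing_indices)
            completed, _ = rm.impute(damaged)
            d_pred = procrustes_distance(
                target.coords, completed.coords, mode="pairwise_opa"
            )
            d_mean = procrustes_distance(
                target.coords, ref_aligned.consensus, mode="pairwise_opa"
            )
        except MorphorecError as exc:
            raise MorphorecError(
                f"{case.name}: target {target_id!r}: {exc}"
            ) from exc
        logger.info(
            "%s target=%s d_true_pred=%.6f d_true_mean=%.6f",
            case.name,
            target_id,
            d_pred,
            d_mean,
        )
        records.append(
            ReconstructionRecord(
                case_name=case.name,
                target_id=target_id,
                d_true_pred=d_pred,
                d_true_mean=d_mean,
                n_reference=len(reference),
            )
        )
    return records


@dataclass(frozen=True)
class CaseTest:
    """Within-case accuracy comparison: d_true_pred vs d_true_mean."""

    ttest: TTestResult
    paired: TTestResult
    mean_d_true_pred: float
    mean_d_true_mean: float


@dataclass(frozen=True)
class StudyReport:
    """All records of a study run plus their inferential statistics."""

    records: tuple[ReconstructionRecord, ...]
    case_tests: Mapping[str, CaseTest]
    anova: AnovaResult
    tukey: tuple[TukeyComparison, ...]
    config: Mapping[str, object]

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    def stats_dict(self) -> dict:
        out: dict = {"cases": {}, "config": dict(self.config)}
        for name, ct in self.case_tests.items():
            out["cases"][name] = {
                "t": ct.ttest.t,
                "df": ct.ttest.df,
                "p": ct.ttest.p,
                "mean_d_true_pred": ct.mean_d_true_pred,
                "mean_d_true_mean": ct.mean_d_true_mean,
                "paired_t": ct.paired.t,
                "paired_p": ct.paired.p,
            }
        out["anova"] = {
            "F": self.anova.F,
            "df1": self.anova.df_between,
            "df2": self.anova.df_within,
            "p": self.anova.p,
        }
        out["tukey"] = [
            {"pair": list(c.pair), "diff": c.diff, "p": c.p} for c in self.tukey
        ]
        return out

    def summary(self) -> str:
        lines = ["Reconstruction accuracy study", "=" * 34]
        for name, ct in self.case_tests.items():
            lines.append(
                f"{name}: mean d(true, predicted) = {ct.mean_d_true_pred:.4f}, "
                f"mean d(true, mean shape) = {ct.mean_d_true_mean:.4f}, "
                f"t = {ct.ttest.t:.2f}, p = {ct.ttest.p:.3g}"
            )
        a = self.anova
        lines.append(
            f"ANOVA across cases: F({a.df_between},{a.df_within}) = "
            f"{a.F:.2f}, p = {a.p:.3g}"
        )
        for c in self.tukey:
            lines.append(
                f"Tukey {c.pair[0]} - {c.pair[1]}: diff = {c.diff:.4f}, "
                f"p = {c.p:.3g}"
            )
        return "\n".join(lines)

    def figure_data_scatter(self) -> pd.DataFrame:
        """Per-target distances (scatter-plot data): one row per record."""
        return self.records_frame()[
            ["case_name", "target_id", "d_true_pred", "d_true_mean"]
        ]

    def figure_data_violin(self) -> pd.DataFrame:
        """Long-format distances by case and comparison type (violin input)."""
        df = self.records_frame()
        long = df.melt(
            id_vars=["case_name", "target_id"],
            value_vars=["d_true_pred", "d_true_mean"],
            var_name="comparison",
            value_name="procrustes_distance",
        )
        long["comparison"] = long["comparison"].map(
            {
                "d_true_pred": "original-reconstructed",
                "d_true_mean": "original-mean",
            }
        )
        return long

    def export(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records_frame().to_csv(out / "records.csv", index=False)
        (out / "stats.json").write_text(json.dumps(self.stats_dict(), indent=2))
        self.figure_data_scatter().to_csv(out / "scatter_data.csv", index=False)
        self.figure_data_violin().to_csv(out / "violin_data.csv", index=False)


def stats_from_records(
    records: Iterable[ReconstructionRecord],
    t_variant: str = "welch",
) -> tuple[dict[str, CaseTest], AnovaResult, tuple[TukeyComparison, ...]]:
    """Recompute every study statistic from raw records (auditable)."""
    records = list(records)
    by_case: dict[str, list[ReconstructionRecord]] = {}
    for r in records:
        by_case.setdefault(r.case_name, []).append(r)
    case_tests = {}
    for name, recs in by_case.items():
        d_pred = np.array([r.d_true_pred for r in recs])
        d_mean = np.array([r.d_true_mean for r in recs])
        case_tests[name] = CaseTest(
            ttest=two_sample_t(d_pred, d_mean, variant=t_variant),
            paired=paired_t(d_pred, d_mean),
            mean_d_true_pred=float(d_pred.mean()),
            mean_d_true_mean=float(d_mean.mean()),
        )
    names = list(by_case)
    groups = [
        np.array([r.d_true_pred for r in by_case[name]]) for name in names
    ]
    result = anova_with_tukey(groups, labels=names)
    return case_tests, result.anova, result.tukey


class DamageStudy:
    """Statsmodels-style front door for the full simulation study.

    Build from a complete dataset and a list of damage cases; ``run(seed)``
    executes every case with deterministically derived per-case seeds and
    returns a :class:`StudyReport`.

    Per-case seeds come from ``numpy.random.SeedSequence(seed).spawn``:
    case i uses child sequence i, so each case is independently
    reproducible.  With ``shared_targets`` one target sample (drawn from
    an extra child sequence) is reused for every case.
    """

    def __init__(
        self,
        dataset: LandmarkDataset,
        cases: Sequence[CaseDefinition] = PAPER_CASES,
        n_targets: int = 30,
        population_filter: str | None = None,
        shared_targets: bool = False,
        slide: bool = True,
        sliding_iterations: int = 3,
        gpa_tol: float = 1e-8,
        t_variant: str = "welch",
    ):
        if population_filter is not None:
            dataset = dataset.filter_population(population_filter)
            if len(dataset) < n_targets + _MIN_EXTRA:
                raise MorphorecError(
                    f"population {population_filter!r} leaves only "
                    f"{len(dataset)} specimens; need at least "
                    f"{n_targets + _MIN_EXTRA}"
                )
        if not cases:
            raise MorphorecError("no damage cases given")
        self.dataset = dataset
        self.cases = tuple(cases)
        self.n_targets = n_targets
        self.population_filter = population_filter
        self.shared_targets = shared_targets
        self.slide = slide
        self.sliding_iterations = sliding_iterations
        self.gpa_tol = gpa_tol
        self.t_variant = t_variant

    def run(self, seed: int) -> StudyReport:
        children = np.random.SeedSequence(seed).spawn(len(self.cases) + 1)
        shared_ids = None
        if self.shared_targets:
            rng = np.random.default_rng(children[-1])
            chosen = rng.choice(
                len(self.dataset), size=self.n_targets, replace=False
            )
            shared_ids = [
                self.dataset[i].specimen_id for i in sorted(chosen)
            ]
        records: list[ReconstructionRecord] = []
        for case, child in zip(self.cases, children):
            records.extend(
                run_case(
                    self.dataset,
                    case,
                    self.n_targets,
                    seed=child,
                    slide=self.slide,
                    sliding_iterations=self.sliding_iterations,
                    gpa_tol=self.gpa_tol,
                    target_ids=shared_ids,
                )
            )
        case_tests, anova, tukey = stats_from_records(
            records, t_variant=self.t_variant
        )
        config = {
            "seed": seed,
            "n_targets": self.n_targets,
            "cases": {c.name: list(c.missing_indices) for c in self.cases},
            "population_filter": self.population_filter,
            "shared_targets": self.shared_targets,
            "slide": self.slide,
            "sliding_iterations": self.sliding_iterations,
            "t_variant": self.t_variant,
            "n_specimens": len(self.dataset),
        }
        return StudyReport(
            records=tuple(records),
            case_tests=case_tests,
            anova=anova,
            tukey=tukey,
            config=config,
        )


def run_study(
    dataset: LandmarkDataset,
    cases: Sequence[CaseDefinition] = PAPER_CASES,
    n_targets: int = 30,
    seed: int = 0,
    population_filter: str | None = None,
    **kwargs,
) -> StudyReport:
    """Functional wrapper over :class:`DamageStudy`."""
    return DamageStudy(
        dataset,
        cases=cases,
        n_targets=n_targets,
        population_filter=population_filter,
        **kwargs,
    ).run(seed)
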