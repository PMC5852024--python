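"""Synthetic multi-year diagnosis registries with planted module structure.

The generator emulates the statistical features the network pipeline relies
on in claims data: heavy-tailed per-disease prevalence, excess co-occurrence
concentrated in disease blocks, and gradual year-to-year drift of block
membership.  Co-occurrence is induced by patient-level latent module
activation — a patient for whom module ``m`` is "active" (a shared risk
factor present) has every disease of that module lifted by a common
multiplicative factor — which yields positive phi-correlation blocks akin to
shared-aetiology comorbidity clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from comorbnet.records import DiagnosisRecord, parse_records

logger = logging.getLogger(__name__)

BACKGROUND_LABEL = "grey"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic registry.

    Diseases not covered by ``module_sizes`` are background ("grey"): their
    indicators are independent of everything.  ``within_module_lift`` = 1
    makes all diseases mutually independent.  ``drift_rate`` is the fraction
    of diseases whose module membership is reassigned between consecutive
    years.
    """

    n_patients: int = 2000
    n_diseases: int = 60
    module_sizes: tuple[int, ...] = (15, 15, 15)
    prevalence_law: str = "log-uniform"  # or "fixed"
    prevalence_range: tuple[float, float] = (0.005, 0.3)
    within_module_lift: float = 4.0
    module_activation_rate: float = 0.3
    n_years: int = 1
    start_year: int = 2000
    drift_rate: float = 0.0
    inpatient_fraction: float = 0.01
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_diseases:
            raise ValueError("module sizes must sum to <= n_diseases")
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi < 1):
            raise ValueError("prevalence_range must lie in (0, 1)")
        if self.within_module_lift < 1:
            raise ValueError("within_module_lift must be >= 1")
        if not (0 <= self.drift_rate <= 1):
            raise ValueError("drift_rate must be in [0, 1]")
        if not (0 < self.module_activation_rate < 1):
            raise ValueError("module_activation_rate must be in (0, 1)")
        if self.prevalence_law not in {"log-uniform", "fixed"}:
            raise ValueError(f"unknown prevalence law {self.prevalence_law!r}")


@dataclass
class SyntheticRegistry:
    """Generated records plus the per-year ground-truth module labels."""

    spec: SyntheticSpec
    records: list[DiagnosisRecord]
    truth: dict[int, pd.Series] = field(default_factory=dict)  # year -> code -> label

    @property
    def years(self) -> list[int]:
        return sorted(self.truth)


def reference_planted_spec(seed: int = 0, *, n_years: int = 1, drift_rate: float = 0.0) -> SyntheticSpec:
    """The reference planted-module study condition.

    Three modules of 15 diseases among 60, lift 4, 2,000 patients, base
    prevalence ~0.05 (log-uniform on [0.03, 0.08], geometric mean ~0.05).
    """
    return SyntheticSpec(
        n_patients=2000,
        n_diseases=60,
        module_sizes=(15, 15, 15),
        prevalence_range=(0.03, 0.08),
        within_module_lift=4.0,
        n_years=n_years,
        drift_rate=drift_rate,
        seed=seed,
    )


def independence_spec(seed: int = 0, *, n_patients: int = 2000) -> SyntheticSpec:
    """Same shape as the reference spec but with lift 1: all independent."""
    return replace(reference_planted_spec(seed), within_module_lift=1.0, n_patients=n_patients)


def _disease_codes(n: int) -> list[str]:
    # Numeric codes from 100 upward, skipping the excluded filter ranges so
    # synthetic registries pass the code-class filter untouched.
    codes: list[str] = []
    v = 100
    while len(codes) < n:
        if not (630 <= v <= 679 or 760 <= v <= 999):
            codes.append(f"{v:03d}")
        v += 1
        if v > 9999:
            raise ValueError("too many diseases requested")
    return codes


def _module_labels(assign: np.ndarray) -> list[str]:
    return [BACKGROUND_LABEL if m < 0 else f"M{m + 1}" for m in assign]


def generate(spec: SyntheticSpec) -> SyntheticRegistry:
    """Generate a registry; deterministic under a fixed seed.

    Per patient and year, each module is active with probability
    ``module_activation_rate``; disease occurrence probability is
    ``base_prevalence * lift`` when the disease's module is active for that
    patient (truncated below 1), else ``base_prevalence``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    codes = _disease_codes(spec.n_diseases)
    patients = [f"P{i:06d}" for i in range(spec.n_patients)]

    if spec.prevalence_law == "log-uniform":
        lo, hi = spec.prevalence_range
        prevalence = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_diseases))
    else:
        prevalence = np.full(spec.n_diseases, spec.prevalence_range[0])

    # year-0 assignment: modules fill a random permutation of the diseases
    assign = np.full(spec.n_diseases, -1, dtype=int)
    perm = rng.permutation(spec.n_diseases)
    pos = 0
    for m, size in enumerate(spec.module_sizes):
        assign[perm[pos : pos + size]] = m
        pos += size

    lifted = prevalence * spec.within_module_lift
    n_trunc = int(np.sum(lifted >= 1.0))
    if n_trunc:
        logger.warning("generate: %d lifted probabilities truncated below 1", n_trunc)
    lifted = np.minimum(lifted, 0.99)

    records: list[DiagnosisRecord] = []
    truth: dict[int, pd.Series] = {}
    for y_off in range(spec.n_years):
        year = spec.start_year + y_off
        if y_off > 0 and spec.drift_rate > 0:
            n_drift = int(round(spec.drift_rate * spec.n_diseases))
            movers = rng.choice(spec.n_diseases, size=n_drift, replace=False)
            # reassign each mover to a uniformly drawn different label
            # (any module or background)
            for d in movers:
                choices = [m for m in range(-1, spec.n_modules) if m != assign[d]]
                assign[d] = choices[rng.integers(len(choices))]
        truth[year] = pd.Series(_module_labels(assign), index=codes, name="module")

        active = rng.random((spec.n_patients, spec.n_modules)) < spec.module_activation_rate
        prob = np.tile(prevalence, (spec.n_patients, 1))
        for m in range(spec.n_modules):
            cols = assign == m
            if cols.any():
                prob[np.ix_(active[:, m], cols)] = lifted[cols]
        occurred = rng.random(prob.shape) < prob
        pat_idx, dis_idx = np.nonzero(occurred)
        settings = np.where(
            rng.random(pat_idx.size) < spec.inpatient_fraction, "inpatient", "outpatient"
        )
        for pi, di, st in zip(pat_idx, dis_idx, settings):
            records.append(DiagnosisRecord(patients[pi], year, codes[di], st))

    return SyntheticRegistry(spec=spec, records=records, truth=truth)


def write_registry(reg: SyntheticRegistry, outdir: str | Path) -> tuple[Path, Path]:
    """Write records and truth as the CSVs the record reader consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec_path = outdir / "records.csv"
    pd.DataFrame(
        [(r.patient_id, r.year, r.code, r.setting) for r in reg.records],
        columns=["patient_id", "year", "code", "setting"],
    ).to_csv(rec_path, index=False)
    truth_path = outdir / "truth.csv"
    rows = [
        (year, code, label)
        for year, labels in sorted(reg.truth.items())
        for code, label in labels.items()
    ]
    pd.DataFrame(rows, columns=["year", "code", "module"]).to_csv(truth_path, index=False)
    return rec_path, truth_path


def read_registry(outdir: str | Path) -> SyntheticRegistry:
    """Round-trip reader for :func:`write_registry` output (truth included)."""
    outdir = Path(outdir)
    records, _ = parse_records(outdir / "records.csv")
    truth_df = pd.read_csv(outdir / "truth.csv", dtype={"code": str})
    truth = {
        int(year): grp.set_index("code")["module"]
        for year, grp in truth_df.groupby("year")
    }
    return SyntheticRegistry(spec=SyntheticSpec(), records=records, truth=truth)
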