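"""Interferon-signature statistics.

Two assays are covered:

* a probe-count panel (NanoString-style): 24 interferon-stimulated-gene
  probes plus reference (housekeeping) probes.  Counts are scaled by the
  geometric mean of each sample's reference probes, converted to fold
  changes against the per-probe median of healthy controls, and summarised
  per sample as the median fold change over the panel.  The positivity
  threshold is the mean of the control scores plus twice their standard
  deviation; samples scoring strictly above it are called positive.

* a qPCR panel: relative expression by the ΔΔCt method.  ΔCt normalises each
  sample's target Ct to the mean of its reference genes; ΔΔCt subtracts the
  mean ΔCt of a calibrator group (mock-treated or healthy donors); relative
  quantity is 2^(−ΔΔCt).

"2 SD" is taken as two sample standard deviations, not two standard errors:
for ~29 controls with scores near 1, 2 SEM would place the threshold
implausibly close to 1 compared with thresholds reported for such panels
(≈2.75); a ``sd_mode`` switch exposes the SEM reading anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientControlsError, NormalizationError

__all__ = [
    "ExpressionMatrix",
    "IfnScoreResult",
    "CtTable",
    "normalize_counts",
    "ifn_score",
    "delta_delta_ct",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ct_table",
    "write_ct_table",
    "write_score_report",
]


@dataclass
class ExpressionMatrix:
    """Samples × probes count (or fold-change) matrix with sample roles.

    ``counts`` rows are samples, columns probes; ``roles`` maps each sample
    to "control" or "case"; ``reference_probes`` are the housekeeping probes
    and are disjoint from the panel (all other columns).
    """

    counts: pd.DataFrame
    roles: pd.Series
    reference_probes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = self.counts.astype(float)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not set(self.roles.index) == set(self.counts.index):
            raise ValueError("roles must cover exactly the samples of the count matrix")
        bad = set(self.roles) - {"control", "case"}
        if bad:
            raise ValueError(f"unknown sample role(s) {sorted(bad)}")
        missing = set(self.reference_probes) - set(self.counts.columns)
        if missing:
            raise ValueError(f"reference probe(s) {sorted(missing)} not in matrix")

    @property
    def panel_probes(self) -> list[str]:
        refs = set(self.reference_probes)
        return [p for p in self.counts.columns if p not in refs]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.counts.index if self.roles[s] == "control"]

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.counts.index if self.roles[s] == "case"]


@dataclass
class IfnScoreResult:
    per_sample_score: pd.Series
    threshold: float
    calls: pd.Series  # "positive" / "negative"
    n_controls: int


@dataclass
class CtTable:
    """Samples × genes Ct values with reference genes and a calibrator group."""

    values: pd.DataFrame
    reference_genes: list[str]
    calibrators: list[str]

    def __post_init__(self):
        self.values = self.values.astype(float)
        if not np.isfinite(self.values.values).all():
            raise ValueError("Ct values must be finite")
        missing = set(self.reference_genes) - set(self.values.columns)
        if missing:
            raise KeyError(f"reference gene(s) {sorted(missing)} not in table")
        missing_samples = set(self.calibrators) - set(self.values.index)
        if missing_samples:
            raise KeyError(f"calibrator sample(s) {sorted(missing_samples)} not in table")


def normalize_counts(matrix: ExpressionMatrix, baseline: str = "median") -> ExpressionMatrix:
    """Reference-probe scaling followed by fold change against controls.

    Each sample's panel counts are divided by the geometric mean of its
    reference-probe counts, then each probe is divided by the control
    ``baseline`` ("median" or "mean") of these scaled values, so control
    fold changes centre on 1.
    """
    if not matrix.reference_probes:
        raise NormalizationError("no reference probes defined")
    refs = matrix.counts[matrix.reference_probes]
    zero_rows = refs.index[(refs <= 0).any(axis=1)]
    if len(zero_rows):
        raise NormalizationError(
            f"non-positive reference count in sample(s): {', '.join(map(str, zero_rows))}"
        )
    geo = np.exp(np.log(refs).mean(axis=1))
    panel = matrix.counts[matrix.panel_probes].div(geo, axis=0)
    controls = matrix.control_samples
    if not controls:
        raise NormalizationError("no control samples to define the fold-change baseline")
    if baseline == "median":
        base = panel.loc[controls].median(axis=0)
    elif baseline == "mean":
        base = panel.loc[controls].mean(axis=0)
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if (base <= 0).any():
        raise NormalizationError("control baseline is zero for at least one probe")
    fold = panel.div(base, axis=1)
    return ExpressionMatrix(counts=fold, roles=matrix.roles.copy(), reference_probes=[])


def ifn_score(normalized: ExpressionMatrix, sd_mode: str = "sd") -> IfnScoreResult:
    """Median-fold-change signature score with a control-derived threshold.

    score(sample) = median over panel probes of the fold change;
    threshold = mean(control scores) + 2·SD(control scores) (sample SD,
    ddof 1; ``sd_mode="sem"`` divides by √n instead).  Calls are strict:
    score > threshold ⇔ positive.
    """
    scores = normalized.counts[normalized.panel_probes].median(axis=1)
    controls = normalized.control_samples
    if len(controls) < 2:
        raise InsufficientControlsError(
            f"need >= 2 control samples to derive a threshold, got {len(controls)}"
        )
    ctrl = scores.loc[controls]
    spread = float(ctrl.std(ddof=1))
    if sd_mode == "sem":
        spread /= np.sqrt(len(controls))
    elif sd_mode != "sd":
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    threshold = float(ctrl.mean()) + 2.0 * spread
    calls = pd.Series(
        np.where(scores > threshold, "positive", "negative"), index=scores.index
    )
    return IfnScoreResult(
        per_sample_score=scores,
        threshold=threshold,
        calls=calls,
        n_controls=len(controls),
    )


def delta_delta_ct(
    ct: CtTable, target_gene: str, calibrators: list[str] | None = None
) -> pd.Series:
    """Relative quantity of ``target_gene`` per sample by the ΔΔCt method."""
    if target_gene not in ct.values.columns:
        raise KeyError(f"gene {target_gene!r} not in Ct table")
    if calibrators is None:
        calibrators = ct.calibrators
    if not calibrators:
        raise ValueError("at least one calibrator sample is required")
    missing = set(calibrators) - set(ct.values.index)
    if missing:
        raise KeyError(f"calibrator sample(s) {sorted(missing)} not in table")
    dct = ct.values[target_gene] - ct.values[ct.reference_genes].mean(axis=1)
    ddct = dct - dct.loc[calibrators].mean()
    return np.power(2.0, -ddct)


# --- plain-text I/O -------------------------------------------------------

def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """TSV with a leading ``role`` column; reference probes marked in a
    ``#reference:`` comment on the first line."""
    with open(path, "w") as fh:
        fh.write("#reference: " + ",".join(matrix.reference_probes) + "\n")
        df = matrix.counts.copy()
        df.insert(0, "role", matrix.roles.loc[df.index])
        df.to_csv(fh, sep="\t", index_label="sample")


def read_expression_matrix(path) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#reference:"):
            raise ValueError("expected a '#reference:' header line")
        refs = [p.strip() for p in first.split(":", 1)[1].split(",") if p.strip()]
        df = pd.read_csv(fh, sep="\t", index_col="sample")
    roles = df.pop("role")
    return ExpressionMatrix(counts=df, roles=roles, reference_probes=refs)


def write_ct_table(ct: CtTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#reference: " + ",".join(ct.reference_genes) + "\n")
        fh.write("#calibrators: " + ",".join(map(str, ct.calibrators)) + "\n")
        ct.values.to_csv(fh, sep="\t", index_label="sample")


def read_ct_table(path) -> CtTable:
    with open(path) as fh:
        ref_line = fh.readline()
        cal_line = fh.readline()
        if not (ref_line.startswith("#reference:") and cal_line.startswith("#calibrators:")):
            raise ValueError("expected '#reference:' and '#calibrators:' header lines")
        refs = [g.strip() for g in ref_line.split(":", 1)[1].split(",") if g.strip()]
        cals = [s.strip() for s in cal_line.split(":", 1)[1].split(",") if s.strip()]
        df = pd.read_csv(fh, sep="\t", index_col="sample")
    return CtTable(values=df, reference_genes=refs, calibrators=cals)


def write_score_report(result: IfnScoreResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# threshold\t{result.threshold:.6f}\n")
        fh.write(f"# n_controls\t{result.n_controls}\n")
        fh.write("sample\tscore\tcall\n")
        for sample in result.per_sample_score.index:
            fh.write(
                f"{sample}\t{result.per_sample_score[sample]:.6f}\t{result.calls[sample]}\n"
            )
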