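"""qPCR relative quantification (ddCt) and concordance with sequencing calls.

Copy number is estimated as 2 x 2^(-ddCt) against a diploid calibrator,
with dCt = mean target Ct - mean reference-gene Ct per sample, assuming
perfect amplification efficiency. A value near 2 is a normal diploid
state; near 0 or 1 a copy loss; around 3 or higher a gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class QpcrMeasurement:
    """Replicate Ct values for one sample against one target CNVR."""

    sample: str
    target_cnvr_id: str
    ct_target: list[float]
    ct_reference: list[float]
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        for name, reps in (("ct_target", self.ct_target),
                           ("ct_reference", self.ct_reference)):
            if len(reps) == 0:
                raise ValueError(f"{self.sample}/{self.target_cnvr_id}: "
                                 f"{name} has no replicates")
            if any(not math.isfinite(c) or c <= 0 for c in reps):
                raise ValueError(f"{self.sample}/{self.target_cnvr_id}: "
                                 f"{name} must be finite and positive")

    @property
    def delta_ct(self) -> float:
        """Replicate-mean target Ct minus replicate-mean reference Ct."""
        return (sum(self.ct_target) / len(self.ct_target)
                - sum(self.ct_reference) / len(self.ct_reference))


def copy_number_ddct(measurement: QpcrMeasurement,
                     calibrator: QpcrMeasurement) -> float:
    """Estimated copy number 2 x 2^(-ddCt) against a diploid calibrator."""
    if calibrator.target_cnvr_id != measurement.target_cnvr_id:
        raise ValueError(
            f"calibrator targets {calibrator.target_cnvr_id!r}, "
            f"measurement targets {measurement.target_cnvr_id!r}"
        )
    ddct = measurement.delta_ct - calibrator.delta_ct
    return 2.0 * 2.0 ** (-ddct)


_LOSS_STATES = frozenset({"hom_del", "het_del", "deletion", "loss"})
_GAIN_STATES = frozenset({"dup", "duplication", "gain"})
_NORMAL_STATES = frozenset({"neutral", "normal"})


def concordance_call(
    cn_estimate: float,
    sequencing_state: str,
    loss_max: float = 1.5,
    gain_min: float = 3.0,
) -> tuple[str, str]:
    """Classify a qPCR copy number and compare with the sequencing state.

    Returns (verdict, qpcr_class) with qpcr_class in {loss, normal, gain}:
    loss when CN <= loss_max, gain when CN >= gain_min, normal in between.
    The verdict is 'concordant' when the class direction matches the
    sequencing-derived state.
    """
    if cn_estimate < 0:
        raise ValueError("copy number estimate must be >= 0")
    if cn_estimate <= loss_max:
        qpcr_class = "loss"
    elif cn_estimate >= gain_min:
        qpcr_class = "gain"
    else:
        qpcr_class = "normal"
    state = sequencing_state.lower()
    if state in _LOSS_STATES:
        expected = "loss"
    elif state in _GAIN_STATES:
        expected = "gain"
    elif state in _NORMAL_STATES:
        expected = "normal"
    else:
        raise ValueError(f"unknown sequencing state {sequencing_state!r}")
    verdict = "concordant" if qpcr_class == expected else "discordant"
    return verdict, qpcr_class


@dataclass
class BatchResult:
    cnvr_id: str
    per_sample: pd.DataFrame
    concordant: bool = field(default=False)


def validate_batch(
    measurements: list[QpcrMeasurement],
    sequencing_states: dict[tuple[str, str], str],
    loss_max: float = 1.5,
    gain_min: float = 3.0,
) -> tuple[list[BatchResult], float]:
    """Per-CNVR qPCR validation against sequencing-derived states.

    ``sequencing_states`` maps (sample, cnvr_id) to the sequencing call.
    Each CNVR batch needs exactly one calibrator. A CNVR counts as
    validated when every non-calibrator sample in its batch is concordant.
    Returns (per-CNVR results, validated fraction in percent).
    """
    by_cnvr: dict[str, list[QpcrMeasurement]] = {}
    for m in measurements:
        by_cnvr.setdefault(m.target_cnvr_id, []).append(m)
    results = []
    n_ok = 0
    for cnvr_id, batch in by_cnvr.items():
        calibrators = [m for m in batch if m.is_calibrator]
        if len(calibrators) != 1:
            raise ValueError(
                f"CNVR {cnvr_id}: need exactly one calibrator, "
                f"got {len(calibrators)}"
            )
        cal = calibrators[0]
        rows = []
        all_ok = True
        for m in batch:
            if m.is_calibrator:
                continue
            cn = copy_number_ddct(m, cal)
            state = sequencing_states[(m.sample, cnvr_id)]
            verdict, qpcr_class = concordance_call(cn, state, loss_max, gain_min)
            all_ok &= verdict == "concordant"
            rows.append({"sample": m.sample, "cn_qpcr": cn,
                         "qpcr_class": qpcr_class, "seq_state": state,
                         "verdict": verdict})
        results.append(BatchResult(cnvr_id=cnvr_id,
                                   per_sample=pd.DataFrame(rows),
                                   concordant=all_ok))
        n_ok += all_ok
    rate = 100.0 * n_ok / len(results) if results else 0.0
    return results, rate


def read_qpcr_tsv(path) -> list[QpcrMeasurement]:
    """Long-format reader: sample, cnvr_id, role, gene, ct (one row per
    replicate; gene is 'target' or 'reference')."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sample, cnvr_id, role), sub in df.groupby(["sample", "cnvr_id", "role"]):
        tgt = sub.loc[sub["gene"] == "target", "ct"].tolist()
        ref = sub.loc[sub["gene"] == "reference", "ct"].tolist()
        out.append(
            QpcrMeasurement(
                sample=str(sample),
                target_cnvr_id=str(cnvr_id),
                ct_target=tgt,
                ct_reference=ref,
                is_calibrator=str(role) == "calibrator",
            )
        )
    return out
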