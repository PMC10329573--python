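"""Shared builders for test samples."""

from uroscreen import CultureObservation, GrowthStatus, Isolate, Sample, SedimentResult
from uroscreen.cohort_model import Adjudication


def make_sample(leuk=10.0, bact=200.0, status="growth", isolates=(), abx=False):
    if status == "growth" and not isolates:
        isolates = [("Escherichia coli", 1e6)]
    return Sample(
        sample_id="t1",
        sediment=SedimentResult(leukocytes=leuk, bacteria=bact),
        culture=CultureObservation(
            growth_status=GrowthStatus(status),
            isolates=tuple(Isolate(o, c) for o, c in isolates),
            antibiotics_needed=abx,
        ),
    )


def adjudicated(leuk, bact, label, **kw):
    """A sample with a pre-set adjudication label, for evaluation-layer tests."""
    s = make_sample(leuk=leuk, bact=bact, **kw)
    s.adjudicated = Adjudication(
        label, "default_positive" if label == "positive" else "no_growth"
    )
    return s
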