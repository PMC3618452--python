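"""Hold-out classification check of OPLS-DA class predictivity.

Per repeat, a fixed number of observations per class (default 3) is held
out, the whole model — unit-variance scaling included — is refitted on
the remainder, and the held-out samples are classified from their
continuous prediction on the 1/2 coding scale: treated if the score
falls strictly below the cutoff (default 1.5), control otherwise (a tie
at exactly the cutoff goes to control).  The report carries per-repeat
correct counts and the average percentage of correct classification.

Test sets are drawn independently per repeat by default (the draws are
seeded and without replacement within a repeat); ``disjoint=True``
partitions each class so no sample is tested twice, which requires
``repeats * test_per_class`` samples per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bucketing import BucketTable
from .opls import OPLSDA

__all__ = ["CvReport", "holdout_classification"]


@dataclass
class RepeatResult:
    test_sample_ids: list[str]
    n_correct: int
    n_test: int


@dataclass
class CvReport:
    repeats: list[RepeatResult] = field(default_factory=list)
    average_percent_correct: float = np.nan
    cutoff: float = 1.5
    seed: int = 0

    def summary(self) -> dict:
        return {
            "average_percent_correct": self.average_percent_correct,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "repeats": [
                {
                    "test_sample_ids": r.test_sample_ids,
                    "n_correct": r.n_correct,
                    "n_test": r.n_test,
                }
                for r in self.repeats
            ],
        }


def holdout_classification(
    table: BucketTable,
    test_per_class: int = 3,
    repeats: int = 4,
    cutoff: float = 1.5,
    seed: int = 0,
    n_orth: int = 1,
    treated_label: str = "treated",
    control_label: str = "control",
    disjoint: bool = False,
) -> CvReport:
    """Repeated hold-out classification of a labeled bucket table."""
    X = table.matrix
    y = np.asarray(table.groups)
    idx_t = np.where(y == treated_label)[0]
    idx_c = np.where(y == control_label)[0]
    for label, idx in ((treated_label, idx_t), (control_label, idx_c)):
        if idx.size <= test_per_class:
            raise ValueError(
                f"class {label!r} has {idx.size} samples; needs more than "
                f"test_per_class={test_per_class}"
            )
        if disjoint and idx.size < repeats * test_per_class:
            raise ValueError(
                f"disjoint mode needs {repeats * test_per_class} samples in "
                f"class {label!r}, found {idx.size}"
            )

    rng = np.random.default_rng(seed)
    if disjoint:
        perm_t = rng.permutation(idx_t)
        perm_c = rng.permutation(idx_c)

    report = CvReport(cutoff=cutoff, seed=seed)
    total_correct = 0
    total_tested = 0
    for rep in range(repeats):
        if disjoint:
            test_t = perm_t[rep * test_per_class : (rep + 1) * test_per_class]
            test_c = perm_c[rep * test_per_class : (rep + 1) * test_per_class]
        else:
            test_t = rng.choice(idx_t, size=test_per_class, replace=False)
            test_c = rng.choice(idx_c, size=test_per_class, replace=False)
        test = np.concatenate([test_t, test_c])
        train = np.setdiff1d(np.arange(X.shape[0]), test)

        model = OPLSDA(
            n_orth=n_orth,
            scale=True,
            cv_folds=0,
            cutoff=cutoff,
            treated_label=treated_label,
            control_label=control_label,
            seed=seed,
        ).fit(X[train], y[train])
        predicted = model.predict_class(X[test])
        n_correct = int(np.sum(predicted == y[test]))
        report.repeats.append(
            RepeatResult(
                test_sample_ids=[table.sample_ids[i] for i in test],
                n_correct=n_correct,
                n_test=int(test.size),
            )
        )
        total_correct += n_correct
        total_tested += int(test.size)
    report.average_percent_correct = 100.0 * total_correct / total_tested
    return report
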