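"""Exception hierarchy for batchalloc."""


class BatchAllocError(Exception):
    """Base class for all batchalloc errors."""


class ProblemValidationError(BatchAllocError, ValueError):
    """The allocation problem violates a structural invariant.

    Raised for nonpositive counts, duplicate treatment labels, or a
    cohort size that does not match the total batch capacity.
    """


class InfeasibleAllocationError(BatchAllocError, RuntimeError):
    """No feasible completion exists from the current allocation state."""


class BudgetExceededError(BatchAllocError, RuntimeError):
    """The exhaustive search space exceeds the configured budget cap."""


class ConfoundedDesignError(BatchAllocError, ArithmeticError):
    """Treatment and batch effects are not separately estimable.

    The information matrix of the intercept + treatment + batch model is
    singular, so contrast variances do not exist.
    """


class ManifestMismatchError(BatchAllocError, ValueError):
    """Sample manifest counts disagree with the problem's cohort."""
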