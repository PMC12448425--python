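"""Exception hierarchy.

Three error classes map to distinct CLI exit codes: I/O and file-format
problems (exit 3), input-validation problems (exit 4), and statistical
degeneracies (exit 5).
"""

from __future__ import annotations

EXIT_IO = 3
EXIT_VALIDATION = 4
EXIT_STATS = 5


class GliomaShapeError(Exception):
    """Base class for all package errors."""

    exit_code = EXIT_VALIDATION


class MaskFormatError(GliomaShapeError):
    """A mask file is missing, unreadable, or has an invalid header."""

    exit_code = EXIT_IO


class GeometryMismatchError(GliomaShapeError):
    """Two grids disagree on dimensions, spacing, or affine transform."""


class ContainmentError(GliomaShapeError):
    """Tumor voxels found outside the brain mask."""

    def __init__(self, n_outside: int):
        self.n_outside = n_outside
        super().__init__(
            f"{n_outside} tumor voxel(s) lie outside the brain mask; "
            "the tumor must be contained in the dura-enclosed region"
        )


class EmptyMaskError(GliomaShapeError):
    """An operation requiring foreground voxels received an empty mask."""


class SpecValidationError(GliomaShapeError):
    """A phantom or cohort specification violates its invariants."""


class SchemaError(GliomaShapeError):
    """A cohort table is missing required columns or has bad values."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort schema violation(s): " + "; ".join(self.problems))


class StatisticalError(GliomaShapeError):
    """Base class for statistical degeneracies."""

    exit_code = EXIT_STATS


class RankDeficiencyError(StatisticalError):
    """Design matrix is rank deficient."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(
            "design matrix is rank deficient; aliased column(s): "
            + ", ".join(self.aliased)
        )


class SeparationError(StatisticalError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(StatisticalError):
    """An iterative fit failed to converge."""

    def __init__(self, n_iter: int, last_change: float):
        self.n_iter = n_iter
        self.last_change = last_change
        super().__init__(
            f"fit did not converge after {n_iter} iterations "
            f"(last max coefficient change {last_change:.3e})"
        )
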