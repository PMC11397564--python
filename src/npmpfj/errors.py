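"""Exception hierarchy for the npmpfj engine."""


class NpmPfjError(Exception):
    """Base class for all engine errors."""


class SchemaError(NpmPfjError):
    """A required column is missing from an input table."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"required column missing from input table: {column!r}")


class RowValidationError(NpmPfjError):
    """One or more rows failed validation; carries the per-row report."""

    def __init__(self, errors):
        self.errors = list(errors)
        ids = ", ".join(str(e.food_id) for e in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(
            f"{len(self.errors)} row(s) failed validation; food_ids: {ids}{more}"
        )


class AlignmentError(NpmPfjError):
    """Parallel sequences that must be index-aligned have different lengths."""


class ConfigurationError(NpmPfjError):
    """A band table, lexicon, or pipeline configuration is missing or invalid."""


class PipelineStageError(NpmPfjError):
    """A pipeline stage failed; names the stage and the offending food ids."""

    def __init__(self, stage: str, message: str, food_ids=()):
        self.stage = stage
        self.food_ids = list(food_ids)
        suffix = f"; food_ids: {', '.join(map(str, self.food_ids))}" if self.food_ids else ""
        super().__init__(f"stage {stage!r}: {message}{suffix}")
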