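"""Exception hierarchy for export parsing and pipeline validation."""


class SmiBridgeError(Exception):
    """Base class for all smibridge errors."""


class SchemaError(SmiBridgeError, ValueError):
    """A required column is missing or cannot be resolved in an input table."""


class ValidationError(SmiBridgeError, ValueError):
    """An input table or parameter violates a structural invariant."""


class FovLookupError(SmiBridgeError, KeyError):
    """A FOV id referenced by a record is absent from the position table."""

    def __init__(self, fov_id):
        super().__init__(fov_id)
        self.fov_id = fov_id

    def __str__(self) -> str:
        return f"unknown FOV id {self.fov_id!r}: not present in the position table"


class StageError(SmiBridgeError, RuntimeError):
    """A pipeline stage failed; carries the stage name for the run report."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
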