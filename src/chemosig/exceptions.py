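"""Exception hierarchy.

``ValidationError`` flags bad configuration or parameters (caller error);
``DataError`` flags inputs that are structurally fine but scientifically
unusable (assay failure, censored IC50 fed to a ratio, degenerate response).
"""


class ChemosigError(Exception):
    """Base class for all package errors."""


class ValidationError(ChemosigError, ValueError):
    """A configuration field or function parameter is out of its documented range."""


class DataError(ChemosigError, ValueError):
    """Input data cannot support the requested computation."""


class PipelineError(ChemosigError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
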