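"""Exception hierarchy for vestibsim."""


class VestibsimError(Exception):
    """Base class for all vestibsim errors."""


class ParameterError(VestibsimError, ValueError):
    """A scalar parameter or configuration value violates its precondition."""


class StructuralError(VestibsimError, ValueError):
    """Array shapes or lengths are inconsistent (e.g. rates vs. weights)."""


class StateError(VestibsimError, RuntimeError):
    """An operation was invoked on a model state that is not ready for it."""


class ConvergenceError(VestibsimError, RuntimeError):
    """Adaptation diverged or produced non-finite intermediates."""


class ConfigError(VestibsimError, ValueError):
    """Experiment configuration failed validation.

    Carries the full list of violations so a user can fix them all at once.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
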