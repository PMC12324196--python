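"""Exception hierarchy and the Issue record shared by validation layers."""

from __future__ import annotations

from dataclasses import dataclass


class CliwrapError(Exception):
    """Base class for all package errors."""


class DescriptorParseError(CliwrapError):
    """The document is not well-formed JSON.

    Carries the decoder's line/column so tooling can point at the byte.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(message + loc)


class DescriptorValidationError(CliwrapError):
    """The document is JSON but violates the dialect; carries Issue list."""

    def __init__(self, issues: list["Issue"]):
        self.issues = issues
        lines = "; ".join(f"{i.path}: {i.message}" for i in issues)
        super().__init__(f"{len(issues)} issue(s): {lines}")


class CrossReferenceError(DescriptorValidationError):
    """A command-template placeholder does not resolve to a parameter."""

    def __init__(self, param_id: str, issues: list["Issue"]):
        self.param_id = param_id
        super().__init__(issues)


class AssignmentError(CliwrapError):
    """A parameter assignment failed check_assignment preconditions."""

    def __init__(self, issues: list["Issue"]):
        self.issues = issues
        lines = "; ".join(f"{i.path}: {i.message}" for i in issues)
        super().__init__(f"{len(issues)} issue(s): {lines}")


class OutputResolutionError(CliwrapError):
    """A required output references an unbound parameter."""


class CodegenError(CliwrapError):
    """A dialect profile is incomplete or an IR construct is unsupported."""


class MangleError(CliwrapError):
    """A raw name has no alphanumeric content to build an identifier from."""


class ToolExecutionError(CliwrapError):
    """A locally executed tool exited nonzero; carries the full argv."""

    def __init__(self, cargs: list[str], returncode: int, stderr_tail: str = ""):
        self.cargs = list(cargs)
        self.returncode = returncode
        self.stderr_tail = stderr_tail
        super().__init__(
            f"command exited with status {returncode}: {' '.join(cargs)}"
            + (f"\n{stderr_tail}" if stderr_tail else "")
        )


class ContainerPlanError(CliwrapError):
    """Container plan requested without a container spec, or plan invariant broken."""


@dataclass(frozen=True, order=True)
class Issue:
    """One validation finding.

    path is a JSON-pointer-style location ("/inputs/2/minimum"); issue lists
    are always sorted by (path, message) so output is deterministic.
    """

    path: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.path}: {self.message}"
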