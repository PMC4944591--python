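"""Structured JSON run reports.

Every CLI run emits a :class:`RunReport`: the command, the seed, the full
resolved configuration and the results, so any run can be replayed.  The
pydantic model doubles as the schema; its JSON Schema export is shipped
as ``report_schema.json`` next to this module and can be regenerated with
:func:`export_schema`.
"""

from __future__ import annotations

import json
from importlib import metadata, resources
from typing import Any

from pydantic import BaseModel, Field


class RunReport(BaseModel):
    """A replayable record of one CLI run."""

    command: str = Field(description="CLI subcommand that produced the report")
    version: str = Field(description="prefattach package version")
    seed: int | None = Field(description="master RNG seed of the run")
    config: dict[str, Any] = Field(description="fully resolved options")
    result: dict[str, Any] = Field(description="command-specific outputs")


def package_version() -> str:
    try:
        return metadata.version("prefattach")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def make_report(command: str, seed: int | None, config: dict, result: dict) -> RunReport:
    return RunReport(
        command=command,
        version=package_version(),
        seed=seed,
        config=config,
        result=result,
    )


def validate_report(data: str | dict) -> RunReport:
    """Validate a serialized report against the schema; raises on mismatch."""
    if isinstance(data, str):
        return RunReport.model_validate_json(data)
    return RunReport.model_validate(data)


def shipped_schema() -> dict:
    """The schema file distributed with the package."""
    text = resources.files("prefattach").joinpath("report_schema.json").read_text()
    return json.loads(text)


def export_schema() -> dict:
    """JSON Schema generated from the report model (should equal the
    shipped file)."""
    return RunReport.model_json_schema()
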