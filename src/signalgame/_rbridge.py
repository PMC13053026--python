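"""Minimal subprocess bridge to R for the mixed-effects fits.

Input tables go out as temporary CSVs, scalar parameters as JSON; the R
snippet must leave a JSON-serializable object named ``result``, which is
written back with jsonlite and returned as parsed Python data.  Any R
error aborts with the captured stderr so that fitting problems surface
loudly rather than silently.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import pandas as pd

__all__ = ["run_r", "r_available"]

_PREAMBLE = """
options(warn = 1)
suppressPackageStartupMessages({{
{libraries}
}})
par <- jsonlite::fromJSON("{params}")
tbl <- function(name) read.csv(file.path("{tmpdir}", paste0(name, ".csv")))
"""

_EPILOGUE = """
jsonlite::write_json(result, "{out}", digits = 12, auto_unbox = TRUE,
                     dataframe = "rows", na = "null")
"""


def r_available() -> bool:
    """True if an Rscript executable is on PATH."""
    return shutil.which("Rscript") is not None


def run_r(
    script: str,
    tables: Optional[Mapping[str, pd.DataFrame]] = None,
    params: Optional[Mapping[str, Any]] = None,
    libraries: tuple = ("jsonlite",),
) -> Any:
    """Run an R snippet and return the parsed JSON it leaves in ``result``.

    ``tables`` are exposed to the snippet via ``tbl("<name>")`` and
    ``params`` via the list ``par``.
    """
    if not r_available():
        raise RuntimeError("Rscript not found on PATH; mixed-model fits require R")
    with tempfile.TemporaryDirectory() as td:
        tmp = Path(td)
        for name, df in (tables or {}).items():
            df.to_csv(tmp / f"{name}.csv", index=False)
        params_path = tmp / "params.json"
        params_path.write_text(json.dumps(dict(params or {})))
        out_path = tmp / "out.json"
        lib_lines = "\n".join(f"library({lib})" for lib in libraries)
        code = (
            _PREAMBLE.format(
                libraries=lib_lines,
                params=params_path.as_posix(),
                tmpdir=tmp.as_posix(),
            )
            + script
            + _EPILOGUE.format(out=out_path.as_posix())
        )
        script_path = tmp / "script.R"
        script_path.write_text(code)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_path.exists():
            tail = (proc.stderr or "")[-2000:]
            raise RuntimeError(f"R fit failed (exit {proc.returncode}):\n{tail}")
        return json.loads(out_path.read_text())
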