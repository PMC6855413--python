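"""Subprocess bridge to R's lme4 for mixed-effects model fitting.

The generalised linear mixed model (logistic stay/switch regression
with per-subject random slopes) is delegated to ``lme4::glmer`` — the
standard tool for this analysis — through a short Rscript invocation
exchanging CSV/JSON. Fits that fail to converge walk down a fallback
ladder of random-effects structures (unstructured -> diagonal ->
intercept-only); singular fits are flagged, not silently accepted.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

__all__ = ["run_mixed_model", "run_glmer_null_batch", "RNotAvailableError"]


class RNotAvailableError(RuntimeError):
    pass


_FIT_TEMPLATE = r"""
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
for (col in c({factor_cols})) if (col %in% names(d)) d[[col]] <- factor(d[[col]])
random_terms <- c({random_terms})
family <- "{family}"
fit_one <- function(rt) {{
  fml <- as.formula(paste("{fixed}", "+", rt))
  if (family == "binomial") {{
    m <- glmer(fml, data = d, family = binomial,
               control = glmerControl(optimizer = "bobyqa", calc.derivs = FALSE))
  }} else {{
    m <- lmer(fml, data = d, REML = TRUE)
  }}
  m
}}
result <- NULL
for (i in seq_along(random_terms)) {{
  m <- tryCatch(fit_one(random_terms[i]), error = function(e) NULL,
                warning = function(w) tryCatch(suppressWarnings(fit_one(random_terms[i])),
                                               error = function(e) NULL))
  if (is.null(m)) next
  msgs <- unlist(m@optinfo$conv$lme4$messages)
  failed <- any(grepl("failed to converge", msgs))
  result <- list(model = m, random = random_terms[i],
                 singular = isSingular(m, tol = 1e-4),
                 conv_failed = failed, messages = msgs, ladder_index = i)
  if (!failed) break
}}
if (is.null(result)) {{
  cat(toJSON(list(error = "all random-effects structures failed"), auto_unbox = TRUE))
}} else {{
  m <- result$model
  fe <- fixef(m)
  V <- as.matrix(vcov(m))
  vc <- as.data.frame(VarCorr(m))
  out <- list(
    coef_names = names(fe),
    estimate = unname(fe),
    vcov = V,
    re_variance = list(grp = vc$grp, var1 = vc$var1, var2 = vc$var2,
                       vcov = vc$vcov),
    singular = result$singular,
    converged = !result$conv_failed,
    messages = if (is.null(result$messages)) character(0) else result$messages,
    random_formula = result$random,
    ladder_index = result$ladder_index,
    n_obs = nobs(m),
    loglik = as.numeric(logLik(m))
  )
  cat(toJSON(out, digits = I(12)))
}}
"""

_NULL_BATCH_TEMPLATE = r"""
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
d$subject <- factor(d$subject)
out <- numeric(0)
for (r in unique(d$replicate)) {{
  di <- d[d$replicate == r, ]
  p <- tryCatch({{
    m <- suppressMessages(suppressWarnings(
      glmer({formula}, data = di, family = binomial,
            control = glmerControl(optimizer = "bobyqa", calc.derivs = FALSE))))
    fe <- fixef(m)
    se <- sqrt(diag(as.matrix(vcov(m))))
    z <- fe["{term}"] / se[which(names(fe) == "{term}")]
    2 * pnorm(-abs(z))
  }}, error = function(e) NA_real_)
  out <- c(out, p)
}}
cat(toJSON(out, digits = I(12)))
"""


def _run_rscript(script: str, workdir: Path) -> dict | list:
    path = workdir / "model.R"
    path.write_text(script)
    try:
        proc = subprocess.run(["Rscript", "--vanilla", str(path)],
                              capture_output=True, text=True, timeout=3600)
    except FileNotFoundError as exc:
        raise RNotAvailableError(
            "Rscript not found on PATH; the mixed logistic backend needs "
            "R with lme4 installed") from exc
    if proc.returncode != 0:
        raise RuntimeError(f"Rscript failed:\n{proc.stderr[-2000:]}")
    text = proc.stdout.strip()
    start = text.find("{")
    start = start if start >= 0 else text.find("[")
    if start < 0:
        raise RuntimeError(f"no JSON in R output:\n{text[-2000:]}\n{proc.stderr[-500:]}")
    return json.loads(text[start:])


def run_mixed_model(df: pd.DataFrame, fixed: str, random_terms: list[str],
                    family: str = "binomial",
                    factor_cols=("subject", "session")) -> dict:
    """Fit fixed + random-effects formula via lme4, walking the fallback ladder.

    Returns a dict with ``coef_names``, ``estimate``, ``vcov``,
    ``re_variance``, ``singular``, ``converged``, ``random_formula``,
    ``ladder_index``, ``n_obs`` and ``loglik``.
    """
    with tempfile.TemporaryDirectory(prefix="twostep_lme4_") as tmp:
        tmp = Path(tmp)
        csv = tmp / "data.csv"
        df.to_csv(csv, index=False)
        script = _FIT_TEMPLATE.format(
            csv=csv.as_posix(), fixed=fixed, family=family,
            factor_cols=", ".join(f'"{c}"' for c in factor_cols),
            random_terms=", ".join(f'"{t}"' for t in random_terms))
        out = _run_rscript(script, tmp)
    if "error" in out:
        raise RuntimeError(f"lme4 fit failed: {out['error']}")
    return out


def run_glmer_null_batch(df: pd.DataFrame, formula: str, term: str) -> list[float]:
    """Fit one glmer per ``replicate`` group in a single R invocation and
    return the Wald p-value of ``term`` for each replicate."""
    with tempfile.TemporaryDirectory(prefix="twostep_lme4_") as tmp:
        tmp = Path(tmp)
        csv = tmp / "data.csv"
        df.to_csv(csv, index=False)
        script = _NULL_BATCH_TEMPLATE.format(csv=csv.as_posix(),
                                             formula=formula, term=term)
        out = _run_rscript(script, tmp)
    return list(out)
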