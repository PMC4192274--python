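"""Single-chain convergence diagnostics and automated burn-in detection.

Three traces are computed from a stored chain: the summed absolute
log-likelihood per record; the count of SNPs whose cumulative posterior
probability exceeds 0.5 at each record; and the Euclidean distance between
the cumulative posterior-mean BayesB effects and the single-SNP-regression
estimates over the current high-PP SNP set.  Burn-in is declared at the
first record from which the log-likelihood trace stays within mean +/- 4 SD
of its final half - an explicit stand-in for visual trace inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayesb import ChainSamples
from .ssr import SsrResult

__all__ = [
    "ConvergenceReport",
    "detect_burn_in",
    "high_pp_count_trace",
    "effect_distance_trace",
    "assess_convergence",
    "write_trace_plots",
]


@dataclass
class ConvergenceReport:
    burn_in: int
    converged: bool
    loglik_trace: np.ndarray
    high_pp_counts: np.ndarray
    effect_distances: np.ndarray
    flags: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "burn_in": int(self.burn_in),
            "converged": bool(self.converged),
            "flags": self.flags,
            "loglik_trace": self.loglik_trace.tolist(),
            "high_pp_counts": self.high_pp_counts.tolist(),
            "effect_distances": self.effect_distances.tolist(),
        }


def detect_burn_in(loglik_trace: np.ndarray, n_sd: float = 4.0) -> tuple[int, bool]:
    """First index from which the trace stays within mean +/- n_sd SD of its last half.

    Returns (index, passed).  If no index qualifies the trace length is
    returned with ``passed = False``.
    """
    trace = np.asarray(loglik_trace, dtype=float)
    if len(trace) < 10:
        raise ValueError("trace too short for burn-in detection (need >= 10 records)")
    if not np.isfinite(trace).all():
        raise ValueError("non-finite values in log-likelihood trace")
    tail = trace[len(trace) // 2 :]
    centre = tail.mean()
    sd = tail.std()
    tol = n_sd * sd
    inside = np.abs(trace - centre) <= tol
    # first index from which every later record is inside the band
    ok_from = len(trace)
    for i in range(len(trace) - 1, -1, -1):
        if inside[i]:
            ok_from = i
        else:
            break
    if ok_from == len(trace):
        return len(trace), False
    return ok_from, True


def high_pp_count_trace(chain: ChainSamples, threshold: float = 0.5) -> np.ndarray:
    """Count of SNPs with cumulative PP > threshold at each record."""
    if chain.n_records < 1:
        raise ValueError("empty chain")
    cum = np.cumsum(chain.delta.astype(np.int64), axis=0)
    denom = np.arange(1, chain.n_records + 1)[:, None]
    return ((cum / denom) > threshold).sum(axis=1)


def effect_distance_trace(
    chain: ChainSamples, ssr_result: SsrResult, pp_threshold: float = 0.5
) -> np.ndarray:
    """Euclidean distance between cumulative BayesB means and SSR estimates.

    At each record the SNP set is those with cumulative PP > pp_threshold;
    the BayesB point effect is the cumulative posterior mean including
    zero draws.  An empty set gives distance 0.
    """
    if list(ssr_result.snp_ids) != list(chain.snp_ids):
        raise ValueError("SSR results do not cover the chain's SNPs in order")
    n_rec = chain.n_records
    denom = np.arange(1, n_rec + 1)[:, None]
    cum_pp = np.cumsum(chain.delta.astype(np.int64), axis=0) / denom
    cum_mean = np.cumsum(chain.effects, axis=0) / denom
    b_hat = np.asarray(ssr_result.effect, dtype=float)
    out = np.empty(n_rec)
    for t in range(n_rec):
        sel = cum_pp[t] > pp_threshold
        diff = cum_mean[t, sel] - b_hat[sel]
        out[t] = np.sqrt(np.sum(diff * diff)) if sel.any() else 0.0
    return out


def assess_convergence(
    chain: ChainSamples, ssr_result: SsrResult | None = None, pp_threshold: float = 0.5
) -> ConvergenceReport:
    """All three diagnostics plus the burn-in decision for one chain."""
    burn_in, passed = detect_burn_in(chain.loglik)
    counts = high_pp_count_trace(chain, pp_threshold)
    if ssr_result is not None:
        dist = effect_distance_trace(chain, ssr_result, pp_threshold)
    else:
        dist = np.zeros(chain.n_records)
    flags = {
        "loglik_stationary": passed,
        "high_pp_plateau": bool(
            len(counts) >= 4 and counts[-1] == counts[max(0, len(counts) * 3 // 4)]
        ),
    }
    return ConvergenceReport(
        burn_in=burn_in,
        converged=passed,
        loglik_trace=np.asarray(chain.loglik, dtype=float),
        high_pp_counts=counts,
        effect_distances=dist,
        flags=flags,
    )


def write_trace_plots(report: ConvergenceReport, out_dir: str | Path) -> list[Path]:
    """Write the three diagnostic traces as SVG files for manual review."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = [
        ("loglik", "summed |log-likelihood|", report.loglik_trace),
        ("high_pp_count", "SNPs with cumulative PP > 0.5", report.high_pp_counts),
        ("effect_distance", "BayesB vs SSR effect distance", report.effect_distances),
    ]
    paths = []
    for name, label, trace in panels:
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(trace, lw=0.8)
        if report.burn_in < len(report.loglik_trace):
            ax.axvline(report.burn_in, color="red", ls="--", lw=0.8, label="burn-in")
            ax.legend(frameon=False)
        ax.set_xlabel("record")
        ax.set_ylabel(label)
        fig.tight_layout()
        p = out / f"{name}.svg"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths


def write_report(report: ConvergenceReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
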