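"""Model/results interface for the cis/trans splicing dissection.

:class:`CisTransSplicing` is built from allele-specific count tables
(parental strains plus F1-hybrid alleles, optionally with mock-hybrid and
downsampled-parental bias controls); :meth:`CisTransSplicing.fit` runs the
full inference — coverage filtering, mock-hybrid consistency filtering,
Bayes-factor divergence calling in both comparisons, permutation FDR, the
Altman–Bland trans test with Storey q-values, and the final per-event
cis/trans classification — and returns a :class:`CisTransResults`.

Typical use::

    from splicedissect import SimConfig, simulate_dataset, CisTransSplicing

    bundle = simulate_dataset(SimConfig(n_events=2000, seed=7))
    model = CisTransSplicing.from_simulation(bundle)
    res = model.fit(seed=7)
    print(res.summary())
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import assign as _assign
from . import cistrans as _ct
from . import divergence as _dv
from . import mock_filter as _mf

logger = logging.getLogger(__name__)

__all__ = ["CisTransSplicing", "CisTransResults"]


class CisTransSplicing:
    """Cis/trans dissection model over allele-specific splicing counts.

    Parameters
    ----------
    counts :
        Long table with columns event_id, sample, replicate, allele,
        n_inclusion, n_exclusion containing the parental samples
        (allele 'pooled') and the hybrid sample (alleles 'B'/'S').
    mock_counts, downsampled_counts :
        Optional bias-control tables (sample 'mock' / 'downsampled',
        alleles 'B'/'S').  When absent and ``assignability`` is given they
        are built at count level from the parental counts.
    events :
        Optional :class:`~splicedissect.events.EventCatalog` for per-type
        summaries and annotation.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        *,
        mock_counts: pd.DataFrame | None = None,
        downsampled_counts: pd.DataFrame | None = None,
        events=None,
        truth: pd.DataFrame | None = None,
        parent_samples: tuple[str, str] = ("parent_B", "parent_S"),
        hybrid_sample: str = "hybrid",
        assignability: float | None = None,
    ):
        required = {"event_id", "sample", "replicate", "allele",
                    "n_inclusion", "n_exclusion"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"counts table lacks columns {sorted(missing)}")
        self.counts = counts
        self.mock_counts = mock_counts
        self.downsampled_counts = downsampled_counts
        self.events = events
        self.truth = truth
        self.parent_samples = parent_samples
        self.hybrid_sample = hybrid_sample
        self.assignability = assignability

    @classmethod
    def from_simulation(cls, bundle: dict) -> "CisTransSplicing":
        """Build from a :func:`~splicedissect.simulate.simulate_dataset` bundle."""
        return cls(
            bundle["counts"],
            events=bundle.get("catalog"),
            truth=bundle.get("truth"),
            assignability=bundle["config"].assignability,
        )

    @classmethod
    def from_tables(cls, counts_path, mock_path=None, downsampled_path=None,
                    **kw) -> "CisTransSplicing":
        from .io import read_table

        mock = read_table(mock_path) if mock_path else None
        down = read_table(downsampled_path) if downsampled_path else None
        return cls(read_table(counts_path), mock_counts=mock,
                   downsampled_counts=down, **kw)

    # ------------------------------------------------------------------
    def _ensure_controls(self, seed):
        """Build count-level mock/downsampled controls if not supplied."""
        if self.mock_counts is None:
            if self.assignability is None:
                return  # no mock filtering possible
            self.mock_counts = _assign.build_mock_f1_counts(
                self.counts, self.assignability, seed=_sub(seed, 11),
                parent_samples={"B": self.parent_samples[0],
                                "S": self.parent_samples[1]},
            )
        if self.downsampled_counts is None:
            self.downsampled_counts = _assign.downsample_parental(
                self.counts, self.mock_counts, seed=_sub(seed, 12),
                parent_samples={"B": self.parent_samples[0],
                                "S": self.parent_samples[1]},
            )

    def fit(
        self,
        bf_min: float = 5.0,
        delta_min: float = 0.1,
        coverage_min: int = 20,
        mock_fdr: float = 0.05,
        n_permutations: int = 100,
        trans_cutoff: float | str = "auto",
        delta_agg: str = "signed-mean",
        use_mock_filter: bool = True,
        seed: int | None = 0,
    ) -> "CisTransResults":
        """Run the full dissection and return a results object.

        ``trans_cutoff='auto'`` applies the same FDR to the trans test as
        the permutation-estimated FDR of the parental divergence threshold
        (the joint BF/|ΔPSI| criterion at ``delta_min``); a float applies
        an absolute q-value cutoff.
        """
        pb, ps = self.parent_samples
        hy = self.hybrid_sample

        # -- mock-hybrid bias filter (pure function of the control data)
        mock_report = None
        kept = None
        if use_mock_filter:
            self._ensure_controls(seed)
        if use_mock_filter and self.mock_counts is not None:
            kept, mock_report = _mf.run_mock_filter(
                self.counts[self.counts["sample"].isin([pb, ps])],
                self.mock_counts, self.downsampled_counts,
                coverage_threshold=coverage_min, fdr=mock_fdr,
                parent_samples={"B": pb, "S": ps},
            )
            logger.info("mock filter kept %d events", len(kept))
        counts = self.counts
        if kept is not None:
            counts = counts[counts["event_id"].isin(kept)]

        # -- divergence calls (coverage filter applied inside)
        parental = _dv.divergence_table(
            counts, pb, ps, bf_min=bf_min, delta_min=delta_min,
            coverage_min=coverage_min, delta_agg=delta_agg,
            comparison="parental",
        )
        allelic = _dv.divergence_table(
            counts, hy, hy, allele1="B", allele2="S",
            bf_min=bf_min, delta_min=delta_min, coverage_min=coverage_min,
            delta_agg=delta_agg, comparison="allelic",
        )
        retained = parental.index.intersection(allelic.index)
        parental = parental.loc[retained]
        allelic = allelic.loc[retained]
        logger.info(
            "retained %d events; parental divergent %d, allelic divergent %d",
            len(retained), int(parental["divergent"].sum()),
            int(allelic["divergent"].sum()),
        )

        # -- permutation FDR grids
        fdr_parental = _dv.permutation_fdr(
            counts, pb, ps, bf_min=bf_min, n_permutations=n_permutations,
            coverage_min=coverage_min, delta_agg=delta_agg, seed=_sub(seed, 21),
        )
        fdr_allelic = _dv.permutation_fdr(
            counts, hy, hy, allele1="B", allele2="S", bf_min=bf_min,
            n_permutations=n_permutations, coverage_min=coverage_min,
            delta_agg=delta_agg, seed=_sub(seed, 22),
        )

        # -- Altman–Bland trans test on pooled counts
        trans = self._trans_tests(counts, retained)

        if trans_cutoff == "auto":
            row = fdr_parental.loc[
                np.isclose(fdr_parental["cutoff"], delta_min)
            ]
            cutoff = float(row["fdr_mean"].iloc[0]) if len(row) and np.isfinite(
                row["fdr_mean"].iloc[0]
            ) else 0.05
        else:
            cutoff = float(trans_cutoff)

        classification = _ct.classify(parental, allelic, trans, cutoff)

        return CisTransResults(
            model=self,
            parental_calls=parental,
            allelic_calls=allelic,
            trans_tests=trans,
            classification=classification,
            fdr_parental=fdr_parental,
            fdr_allelic=fdr_allelic,
            mock_report=mock_report,
            params=dict(
                bf_min=bf_min, delta_min=delta_min, coverage_min=coverage_min,
                mock_fdr=mock_fdr, n_permutations=n_permutations,
                trans_cutoff=cutoff, delta_agg=delta_agg, seed=seed,
            ),
        )

    def _trans_tests(self, counts, retained) -> pd.DataFrame:
        pb, ps = self.parent_samples
        sides = {}
        for key, sample, allele in (
            ("pB", pb, None), ("pS", ps, None),
            ("aB", self.hybrid_sample, "B"), ("aS", self.hybrid_sample, "S"),
        ):
            ids, inc, exc = _dv.counts_to_arrays(counts, sample, allele)
            keep = pd.Index(ids).get_indexer(retained)
            sides[key] = (inc[keep].sum(axis=1), exc[keep].sum(axis=1))
        lrp, sep = _ct.ratio_and_se(*sides["pB"], *sides["pS"])
        lra, sea = _ct.ratio_and_se(*sides["aB"], *sides["aS"])
        z, p = _ct.trans_z_test(lrp, sep, lra, sea)
        q = _ct.storey_qvalues(p)
        return pd.DataFrame(
            {
                "log_ratio_parental": lrp, "se_parental": sep,
                "log_ratio_allelic": lra, "se_allelic": sea,
                "z_value": z, "p_value": p, "q_value": q,
            },
            index=retained,
        )


def _sub(seed, offset):
    if seed is None:
        return None
    return int(np.random.SeedSequence([int(seed), offset]).generate_state(1)[0]
               % (2**31 - 1))


class CisTransResults:
    """Estimates, per-event classification and diagnostics of a fitted model."""

    def __init__(self, model, parental_calls, allelic_calls, trans_tests,
                 classification, fdr_parental, fdr_allelic, mock_report,
                 params):
        self.model = model
        self.parental_calls = parental_calls
        self.allelic_calls = allelic_calls
        self.trans_tests = trans_tests
        self.classification = classification
        self.fdr_parental = fdr_parental
        self.fdr_allelic = fdr_allelic
        self.mock_report = mock_report
        self.params = params

    # ------------------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """Joined per-event result table."""
        out = self.classification.join(
            self.trans_tests[["z_value", "p_value", "q_value"]]
        )
        out = out.join(self.parental_calls[["mean_delta"]]
                       .rename(columns={"mean_delta": "delta_parental"}))
        out = out.join(self.allelic_calls[["mean_delta"]]
                       .rename(columns={"mean_delta": "delta_allelic"}))
        if self.model.events is not None:
            out["as_type"] = [
                self.model.events[e].as_type if e in self.model.events else "NA"
                for e in out.index
            ]
        return out

    @property
    def category_counts(self) -> pd.Series:
        return self.classification["category"].value_counts()

    def summary(self) -> str:
        """Human-readable breakdown of the dissection."""
        n_retained = len(self.classification)
        n_par = int(self.classification["parental_divergent"].sum())
        n_all = int(self.classification["allelic_divergent"].sum())
        cats = self.category_counts
        crit = (f"parental divergent (BF>{self.params['bf_min']:g}, "
                f"|dPSI|>{self.params['delta_min']:g})")
        lines = [
            "Cis/trans dissection of alternative-splicing divergence",
            "=" * 60,
            f"{'events retained after filtering':<40s} {n_retained:>7d}",
            f"{crit:<40s} {n_par:>7d} ({_pct(n_par, n_retained)}%)",
            f"{'allelic divergent':<40s} {n_all:>7d}"
            f" ({_pct(n_all, n_retained)}%)",
            f"{'trans q-value cutoff':<40s} {self.params['trans_cutoff']:>10.4g}",
            "-" * 60,
        ]
        for cat in ("cis_only", "cis_and_trans", "trans_only", "unexplained",
                    "conserved"):
            n = int(cats.get(cat, 0))
            lines.append(f"  {cat:<38s} {n:>7d} ({_pct(n, n_retained)}%)")
        if self.model.events is not None:
            lines.append("-" * 60)
            lines.append("per AS type (divergent / retained):")
            tab = self.table
            for as_type, grp in tab.groupby("as_type"):
                nd = int(grp["parental_divergent"].sum())
                lines.append(
                    f"  {as_type:<5s} {nd:>5d} / {len(grp):<6d}"
                    f" ({_pct(nd, len(grp))}%)"
                )
        return "\n".join(lines)

    def evaluate_against_truth(self) -> pd.DataFrame:
        """Cross-tabulate called categories against simulated architectures."""
        if self.model.truth is None:
            raise ValueError("model carries no ground truth")
        truth = self.model.truth.set_index("event_id")["architecture"]
        tab = self.classification.join(truth, how="left")
        return pd.crosstab(tab["architecture"], tab["category"])

    def plot_divergence(self, ax=None):
        """Parental vs allelic ΔPSI scatter, coloured by category."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        tab = self.table
        colors = {
            "conserved": "0.8", "unexplained": "0.4", "cis_only": "tab:red",
            "cis_and_trans": "tab:purple", "trans_only": "tab:blue",
        }
        for cat, grp in tab.groupby("category"):
            ax.scatter(grp["delta_allelic"], grp["delta_parental"],
                       s=8, label=cat, c=colors.get(cat, "k"), alpha=0.6)
        ax.axline((0, 0), slope=1, color="0.6", lw=0.8)
        ax.set_xlabel("allelic ΔPSI (F1 hybrid)")
        ax.set_ylabel("parental ΔPSI")
        ax.legend(fontsize=7)
        return ax


def _pct(k, n):
    return f"{100.0 * k / n:.1f}" if n else "0.0"
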