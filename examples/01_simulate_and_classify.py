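"""Generate a synthetic gut metaproteome and classify tryptic status.

Builds a ground-truthed bundle (protein FASTA, three engines' peptide
tables, taxonomy and function maps), applies the PEP < 0.05 filter and
the three-engine consensus rule, and assigns each peptide FULL /
SEMI_N / SEMI_C / NON tryptic status.
"""

import semipep as sp
from semipep.tryptic import TrypticStatus

cfg = sp.SimConfig(seed=0)
bundle = sp.simulate_dataset(cfg)
print(f"simulated {len(bundle.db.entries)} proteins, "
      f"{len(bundle.pool)} peptides in the identification pool")

filtered = [sp.filter_pep(bundle.engines[e], 0.05)
            for e in sorted(bundle.engines)]
consensus = sp.intersect_engines(filtered, "maxquant")
statuses = sp.classify_all(consensus)

n = len(statuses)
for status in TrypticStatus:
    count = sum(1 for v in statuses.values() if v is status)
    print(f"  {status.value:7s} {count:5d}  ({100 * count / n:.1f}%)")

semi = sum(1 for v in statuses.values()
           if v in (TrypticStatus.SEMI_N, TrypticStatus.SEMI_C))
print(f"{semi} of {n} consensus peptides ({100 * semi / n:.1f}%) are "
      "semi-tryptic -- the proxy for endogenous proteolysis. Real gut "
      "metaproteomes show roughly 12-26% depending on body site.")
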