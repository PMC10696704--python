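"""Compute DIC assimilation rates from a 13C-bicarbonate incubation.

Builds one worked incubation bottle, computes its rate through the
delta-notation chain, and then averages the replicate rates measured at
the two Kueishantao vent sites into the standard rate table.
"""

from sipautotroph import TracerIncubation, dic_assimilation_rate, report_rate_table
from sipautotroph.datasets import VENT_RATE_REPLICATES

# One bottle: POC stayed at 10 umol C/L while delta-13C rose from -25
# to +100 permil over a 1-day incubation with 3 mM added bicarbonate
# (Cs = 3000 umol/L) on top of 2000 umol/L ambient DIC.
inc = TracerIncubation(
    delta_0=-25.0, delta_t=100.0, poc_0=10.0, poc_t=10.0,
    t=1.0, ca_dic=2000.0, cs_dic=3000.0,
)
res = dic_assimilation_rate(inc)
print(f"worked incubation rate : {res.rate:.6f} umol C/L/day")
print(f"detection limit        : {res.detection_limit:.2e} umol C/L/day")
print("-> the 125 permil delta-13C shift corresponds to ~0.0229 umol C/L/day")
print("   of total DIC assimilation after the (Ca+Cs)/Cs tracer-dilution correction.\n")

# Replicate rates per condition (three tracer treatments behave as
# biological replicates); BDL replicates are skipped, all-BDL prints ND.
table = report_rate_table(VENT_RATE_REPLICATES)
print(table.to_string(index=False))
print("\n-> white-vent (WV) rates are ~1.5-2.1 umol C/L/day at every temperature;")
print("   yellow-vent (YV) rates collapse with temperature at its lower pH.")
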