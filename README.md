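# cropcast

Weather-based crop yield prediction through exhaustive selection of
time-aggregated weather features for per-district multiple linear
regressions — with strictly out-of-sample feature screening, evaluation,
model selection, prediction, and area-weighted regional aggregation.

The pipeline has five stages, run separately for every target year so that
no information from the target year's yields leaks into feature selection or
fitting:

1. **prospector** — aggregate each weather variable over every contiguous
   2–6-month window of the 12-month pre-harvest season (45 windows per
   variable, e.g. `tas0506` = May–June temperature mean), exhaustively rank
   all ≤4-feature regressions per district by in-sample fit (target year
   censored), and screen features whose occurrence count among the top-23
   regressions per district exceeds the 99.9 % binomial quantile of the
   pure-chance null.
2. **workhorse** — score every valid combination (sizes 0–4, same-variable
   windows must not overlap, trend-only included) of the screened features
   by the Pearson correlation between observed yields and leave-one-out
   predictions, per district.
3. **goldpan** — build a candidate pool from globally best combinations and
   "subset heroes" (best mean over their own top fraction of districts, down
   to 10 %), then assign each district its best pool member.
4. **predictor** — hindcast (target-year yield censored) or forecast
   (all years used) each district from its assigned regression.
5. **aggregation** — growing-area-weighted regional averages with
   ±1.96·sd(error) uncertainty bands (forecast bands use a t-quantile and
   are centred on the mean past error), plus R²_val = 1 − SSE/SST and RMSE.

A synthetic-data module generates district panels with known planted window
effects so the full pipeline is testable without external data.

## CLI

```sh
cropcast simulate --districts 60 --years 25 --seed 42 --out simdata/
cd simdata
cropcast prospect  --config control.yaml --target-year 2005
cropcast evaluate  --config control.yaml --target-year 2005
cropcast select    --config control.yaml --target-year 2005
cropcast predict   --config control.yaml --target-year 2005
cropcast run-all   --config control.yaml          # all stages, all years
cropcast aggregate --config control.yaml          # stage 5 from files
```

All inputs and outputs are tab-delimited ASCII tables with a header row and
`NA` for missing values; the control file is YAML (see
`cropcast.interface.config.ControlFile` for keys and defaults — cut-off
month June, minimum 17 yield years per district, top 23 regressions
retained, up to 4 features, 99.9 % screening confidence).

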