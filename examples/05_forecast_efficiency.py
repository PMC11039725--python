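"""Forecast a monthly efficiency series with the attention Bi-LSTM.

Trains on the first 80% of a seasonal efficiency series and reports
held-out error metrics plus the attention weights of the last window.
"""

import numpy as np

from fleetdea import ForecastConfig, forecast_series

t = np.arange(96)
series = 0.5 + 0.3 * np.sin(2 * np.pi * t / 12)   # noiseless seasonal benchmark

report = forecast_series(series, ForecastConfig(window=6, epochs=200, seed=7))
print(f"held-out MSE  = {report.mse:.5f}")
print(f"held-out RMSE = {report.rmse:.5f}")
print(f"held-out MAE  = {report.mae:.5f}")
print(f"held-out MAPE = {report.mape:.4%}")
print(f"held-out R^2  = {report.r2:.4f}")
print(f"final training loss = {report.final_training_loss:.6f}")
print(f"\nlast test window attention weights (sum to 1): "
      f"{np.round(report.attention[-1], 3)}")
print("\nR^2 near 1 and MSE near 0 mean the network has learned the "
      "seasonal pattern; the attention row shows which months of the "
      "window drive the prediction.")
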