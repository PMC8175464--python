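{
 "description": "Calibration of the tortuous-network generator: realized length-weighted mean capillary curvature (um^-1) vs von Mises-Fisher direction persistence, measured by the full generate->summarize pipeline at 1 um step (30 paths x 200 um mean length per point, seeds 20210603+i).",
 "step_um": 1.0,
 "table": [
  {
   "persistence": 150.0,
   "mean_curvature": 0.10279998286043707
  },
  {
   "persistence": 230.5176791515922,
   "mean_curvature": 0.08234412667034366
  },
  {
   "persistence": 354.25600267624264,
   "mean_curvature": 0.06665824308731717
  },
  {
   "persistence": 544.4151437496516,
   "mean_curvature": 0.05370360039376616
  },
  {
   "persistence": 836.6487695476675,
   "mean_curvature": 0.043044179226103534
  },
  {
   "persistence": 1285.7488841410905,
   "mean_curvature": 0.03495451014643652
  },
  {
   "persistence": 1975.9189916263588,
   "mean_curvature": 0.028402250127074098
  },
  {
   "persistence": 3036.561734275083,
   "mean_curvature": 0.022783628417806605
  },
  {
   "persistence": 4666.541090570839,
   "mean_curvature": 0.01812816401866629
  },
  {
   "persistence": 7171.46814575953,
   "mean_curvature": 0.014786544467355394
  },
  {
   "persistence": 11021.001287133726,
   "mean_curvature": 0.011943956392473946
  },
  {
   "persistence": 16936.904257578524,
   "mean_curvature": 0.009624327343096255
  },
  {
   "persistence": 26028.37240979817,
   "mean_curvature": 0.00769632248551686
  },
  {
   "persistence": 40000.0,
   "mean_curvature": 0.006232891263777703
  }
 ]
}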