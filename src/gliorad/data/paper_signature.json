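{
 "features": [
  "CET1|LLH|glcm|sum_entropy|d3|mean",
  "FLAIR|LHH|firstorder|mean_absolute_deviation",
  "FLAIR|orig|glrlm|hgre|std",
  "ADC|HHH|firstorder|skewness",
  "CBV|HHL|glcm|entropy|d1|std",
  "CBV|HHH|glrlm|lrhge|mean"
 ],
 "coefficients": [
  -0.07896580,
  -0.06340327,
  -0.09125977,
  -0.05745977,
  0.03145506,
  -0.08185888
 ],
 "lambda": null,
 "cutoff": -0.07,
 "standardization": {
  "mean": {
   "CET1|LLH|glcm|sum_entropy|d3|mean": 0.0,
   "FLAIR|LHH|firstorder|mean_absolute_deviation": 0.0,
   "FLAIR|orig|glrlm|hgre|std": 0.0,
   "ADC|HHH|firstorder|skewness": 0.0,
   "CBV|HHL|glcm|entropy|d1|std": 0.0,
   "CBV|HHH|glrlm|lrhge|mean": 0.0
  },
  "sd": {
   "CET1|LLH|glcm|sum_entropy|d3|mean": 1.0,
   "FLAIR|LHH|firstorder|mean_absolute_deviation": 1.0,
   "FLAIR|orig|glrlm|hgre|std": 1.0,
   "ADC|HHH|firstorder|skewness": 1.0,
   "CBV|HHL|glcm|entropy|d1|std": 1.0,
   "CBV|HHH|glrlm|lrhge|mean": 1.0
  },
  "dropped": []
 },
 "provenance": {
  "source": "published six-feature multiparametric MR radiomics signature",
  "note": "identity standardization: apply to already-standardized features"
 }
}
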