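# Total US surgical aortic valve replacement volumes (all prosthesis types,
# isolated + combined), 2012-2020, approximated from STS Adult Cardiac Surgery
# Database annual summaries (rounded to the nearest thousand; 2020 reflects the
# pandemic dip). The default scenario multiplies these by the bioprosthetic
# usage fraction (0.80).
year,count,provenance
2012,65000,observed
2013,64000,observed
2014,63000,observed
2015,62000,observed
2016,61000,observed
2017,60000,observed
2018,59000,observed
2019,57000,observed
2020,52000,observed
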