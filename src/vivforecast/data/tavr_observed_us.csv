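# Observed annual US TAVR implant volumes (commercial + trial), assembled from
# public STS/ACC TVT Registry annual-report summaries.
# 2012-2019: Carroll JD et al., "STS-ACC TVT Registry of Transcatheter Aortic
#            Valve Replacement", J Am Coll Cardiol / Ann Thorac Surg 2020.
# 2020-2022: approximate values from subsequent registry press summaries and
#            annual-report figures (rounded; the registry does not publish a
#            machine-readable series).
# These are literature approximations shipped as the default scenario input;
# replace with registry exports via the `tavr_volumes` config key if available.
year,count,provenance
2012,4627,observed
2013,9246,observed
2014,16295,observed
2015,24808,observed
2016,34898,observed
2017,44000,observed
2018,57600,observed
2019,72991,observed
2020,73500,observed
2021,84000,observed
2022,94000,observed
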