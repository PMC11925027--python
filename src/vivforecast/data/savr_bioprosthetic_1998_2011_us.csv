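# Annual US bioprosthetic surgical AVR volumes, 1998-2011, approximated from
# published surgical-series trend reports (rising bioprosthetic share of a
# slowly growing surgical AVR volume over the 2000s).
# These are literature approximations shipped as the default scenario input.
year,count,provenance
1998,30000,observed
1999,31200,observed
2000,32500,observed
2001,33700,observed
2002,35000,observed
2003,36200,observed
2004,37500,observed
2005,38700,observed
2006,40000,observed
2007,41200,observed
2008,42500,observed
2009,43700,observed
2010,45000,observed
2011,46000,observed
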