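year,theil
2008,0.1779
2009,0.1704
2010,0.1614
2011,0.1493
2012,0.1818
2013,0.1463
2014,0.1494
2015,0.1594
2016,0.1468
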