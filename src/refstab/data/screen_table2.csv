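species,gene,status,efficiency_pct
zebra finch,18S,measured,102.5
zebra finch,ABL,measured,93.9
zebra finch,GAPDH,measured,70.8
zebra finch,GUSB,measured,100.0
zebra finch,HMBS,measured,96.3
zebra finch,HPRT,measured,93.5
zebra finch,PGK1,measured,94.0
zebra finch,RPL13,nd,
zebra finch,RPL19,nd,
zebra finch,RPS7,measured,100.9
zebra finch,SDHA,measured,103.3
zebra finch,TFRC,measured,103.6
zebra finch,VIM,measured,95.8
zebra finch,YWHAZ,measured,96.6
cockatiel,18S,nd,
cockatiel,ABL,measured,89.9
cockatiel,GAPDH,nd,
cockatiel,GUSB,measured,91.3
cockatiel,HMBS,nd,
cockatiel,HPRT,measured,84.4
cockatiel,PGK1,measured,96.8
cockatiel,RPL13,nt,
cockatiel,RPL19,nt,
cockatiel,RPS7,measured,92.8
cockatiel,SDHA,measured,95.8
cockatiel,TFRC,measured,92.3
cockatiel,VIM,measured,95.5
cockatiel,YWHAZ,measured,84.6
white-tailed eagle,18S,nd,
white-tailed eagle,ABL,measured,94.0
white-tailed eagle,GAPDH,nd,
white-tailed eagle,GUSB,measured,96.4
white-tailed eagle,HMBS,measured,94.4
white-tailed eagle,HPRT,measured,89.2
white-tailed eagle,PGK1,measured,94.2
white-tailed eagle,RPL13,nt,
white-tailed eagle,RPL19,nt,
white-tailed eagle,RPS7,measured,93.0
white-tailed eagle,SDHA,measured,97.9
white-tailed eagle,TFRC,measured,100.4
white-tailed eagle,VIM,measured,98.1
white-tailed eagle,YWHAZ,measured,93.0
Humboldt penguin,18S,nd,
Humboldt penguin,ABL,measured,94.3
Humboldt penguin,GAPDH,nd,
Humboldt penguin,GUSB,measured,93.0
Humboldt penguin,HMBS,measured,84.7
Humboldt penguin,HPRT,measured,87.5
Humboldt penguin,PGK1,measured,93.6
Humboldt penguin,RPL13,nt,
Humboldt penguin,RPL19,nt,
Humboldt penguin,RPS7,measured,95.9
Humboldt penguin,SDHA,measured,94.5
Humboldt penguin,TFRC,measured,97.7
Humboldt penguin,VIM,measured,98.8
Humboldt penguin,YWHAZ,measured,94.8
common crane,18S,nd,
common crane,ABL,nw,
common crane,GAPDH,nd,
common crane,GUSB,measured,90.8
common crane,HMBS,measured,91.0
common crane,HPRT,measured,89.0
common crane,PGK1,measured,94.2
common crane,RPL13,nt,
common crane,RPL19,nt,
common crane,RPS7,measured,94.8
common crane,SDHA,measured,86.1
common crane,TFRC,measured,94.6
common crane,VIM,measured,98.8
common crane,YWHAZ,measured,95.8
chicken,18S,measured,107.6
chicken,ABL,measured,93.3
chicken,GAPDH,measured,72.7
chicken,GUSB,measured,90.3
chicken,HMBS,measured,94.3
chicken,HPRT,measured,81.2
chicken,PGK1,measured,88.3
chicken,RPL13,nd,
chicken,RPL19,nd,
chicken,RPS7,measured,89.8
chicken,SDHA,measured,96.2
chicken,TFRC,measured,87.8
chicken,VIM,measured,100.8
chicken,YWHAZ,measured,99.7
turkey,18S,nd,
turkey,ABL,measured,92.4
turkey,GAPDH,nd,
turkey,GUSB,measured,96.0
turkey,HMBS,measured,98.3
turkey,HPRT,measured,88.0
turkey,PGK1,measured,95.9
turkey,RPL13,nt,
turkey,RPL19,nt,
turkey,RPS7,measured,91.3
turkey,SDHA,measured,96.8
turkey,TFRC,measured,99.4
turkey,VIM,measured,101.0
turkey,YWHAZ,measured,98.8
mallard,18S,nd,
mallard,ABL,nw,
mallard,GAPDH,nd,
mallard,GUSB,measured,83.4
mallard,HMBS,nw,
mallard,HPRT,measured,86.7
mallard,PGK1,measured,94.4
mallard,RPL13,nt,
mallard,RPL19,nt,
mallard,RPS7,measured,97.9
mallard,SDHA,measured,91.1
mallard,TFRC,measured,95.7
mallard,VIM,measured,99.5
mallard,YWHAZ,measured,94.7
ostrich,18S,nd,
ostrich,ABL,measured,93.1
ostrich,GAPDH,nd,
ostrich,GUSB,measured,99.3
ostrich,HMBS,measured,96.9
ostrich,HPRT,measured,85.8
ostrich,PGK1,measured,96.3
ostrich,RPL13,nd,
ostrich,RPL19,nd,
ostrich,RPS7,measured,85.3
ostrich,SDHA,measured,98.5
ostrich,TFRC,measured,85.9
ostrich,VIM,measured,101.8
ostrich,YWHAZ,measured,94.9
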