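# Curated snapshot of public-suffix rules used for registered-domain
# extraction.  One suffix per line; '!' marks special-use/non-routable
# suffixes whose hostnames are rejected outright.  Any TLD not listed is
# treated as its own public suffix (the default rule).  The documentation
# TLD 'example' is deliberately listed as routable so synthetic corpora
# built on *.example domains survive normalization.
com
net
org
edu
gov
mil
int
io
co
ai
app
dev
tv
me
info
biz
xyz
cloud
online
site
store
us
uk
co.uk
org.uk
ac.uk
gov.uk
net.uk
au
com.au
net.au
org.au
edu.au
jp
co.jp
ne.jp
or.jp
ac.jp
br
com.br
net.br
org.br
de
fr
nl
it
es
pt
se
no
fi
dk
ch
at
be
ie
pl
cz
ru
com.ru
cn
com.cn
net.cn
org.cn
in
co.in
net.in
org.in
kr
co.kr
tw
com.tw
hk
com.hk
sg
com.sg
ca
mx
com.mx
ar
com.ar
cl
nz
co.nz
za
co.za
tr
com.tr
example
!local
!localhost
!internal
!intranet
!lan
!home
!corp
!arpa
!invalid
!test
!onion
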